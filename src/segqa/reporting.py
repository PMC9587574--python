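"""Aggregation of per-case outlier inventories and the end-to-end pipeline.

Per-model outlier reports are condensed into a model table (counts per
structure plus pooled size/distance statistics of each model's PTV outliers)
and into summary statistics: grand totals before and after PTV construction,
mean-of-model-means with population standard deviation for distance and
size, per-model averages over the non-ensemble models, and the relative
reduction of PTV outliers achieved by the ensemble.

``run_pipeline`` drives the whole synthetic study: phantom cases, per-model
predictions with injected outliers, majority-vote fusion, PTV construction,
outlier inventory, the dose surrogate with DVH and gamma checks, and
deterministic CSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import refdata
from .components import volume_difference_percent
from .dosimetry import GammaCriteria, dvh_metrics, gamma_analysis, healthy_brain
from .ensemble import vote_per_structure
from .grid import GridSpec
from .phantom import PredictionSetConfig, make_head_phantom, simulate_model_predictions, synthesize_dose
from .targets import build_ptv, outlier_report

__all__ = [
    "ModelTable",
    "SummaryStats",
    "PipelineConfig",
    "build_model_table",
    "summarize",
    "build_volume_table",
    "run_pipeline",
]


@dataclass
class ModelTable:
    """Per-model outlier counts and pooled PTV-outlier statistics."""

    frame: pd.DataFrame  # indexed by model name

    COLUMNS = [
        "gtv_outliers",
        "edema_outliers",
        "ptv_outliers",
        "mean_distance_mm",
        "median_distance_mm",
        "mean_size_mm3",
        "median_size_mm3",
    ]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"model table is missing columns: {missing}")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, float_format="%.6g")

    @classmethod
    def from_csv(cls, path) -> "ModelTable":
        return cls(pd.read_csv(path, index_col=0))


@dataclass
class SummaryStats:
    total_gtv_edema_outliers: int
    total_ptv_outliers: int
    ensemble_ptv_outliers: int
    mean_of_model_mean_distance_mm: float
    popsd_of_model_mean_distance_mm: float
    mean_of_model_mean_size_mm3: float
    popsd_of_model_mean_size_mm3: float
    mean_combined_per_model: float
    mean_ptv_per_model: float
    ptv_reduction_percent: float

    def to_dict(self) -> dict:
        return asdict(self)


def build_model_table(reports: dict[str, list]) -> ModelTable:
    """Aggregate per-case outlier reports into one row per model.

    ``reports`` maps a model name to its list of per-case reports (structure
    name -> Decomposition, expecting GTV, edema and PTV).  Counts are summed
    over cases; size/distance statistics pool that model's PTV outliers
    across all cases.  All models must cover the same case list.
    """
    if not reports:
        raise ValueError("no model reports given")
    n_cases = {name: len(cases) for name, cases in reports.items()}
    if len(set(n_cases.values())) != 1:
        raise ValueError(f"models cover inconsistent case lists: {n_cases}")

    rows = {}
    for name, cases in reports.items():
        gtv = sum(rep["GTV"].n_outliers for rep in cases)
        edema = sum(rep["edema"].n_outliers for rep in cases)
        ptv_recs = [o for rep in cases for o in rep["PTV"].outliers]
        sizes = np.array([o.voxel_volume_mm3 for o in ptv_recs])
        dists = np.array([o.distance_to_main_mm for o in ptv_recs])
        rows[name] = {
            "gtv_outliers": gtv,
            "edema_outliers": edema,
            "ptv_outliers": len(ptv_recs),
            "mean_distance_mm": float(dists.mean()) if len(ptv_recs) else float("nan"),
            "median_distance_mm": float(np.median(dists)) if len(ptv_recs) else float("nan"),
            "mean_size_mm3": float(sizes.mean()) if len(ptv_recs) else float("nan"),
            "median_size_mm3": float(np.median(sizes)) if len(ptv_recs) else float("nan"),
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")[ModelTable.COLUMNS]
    frame.index.name = "model"
    return ModelTable(frame)


def summarize(table: ModelTable, ensemble_name: str = refdata.ENSEMBLE_NAME) -> SummaryStats:
    """Abstract-level aggregate statistics from a model table.

    Totals and the distance/size mean-of-means (with population standard
    deviation over the per-model means) run over *all* models including the
    ensemble; the per-model averages and the PTV-reduction denominator use
    the non-ensemble models only:

        reduction = 100 * (mean PTV outliers per model - ensemble PTV count)
                        / (mean PTV outliers per model)
    """
    f = table.frame
    if ensemble_name not in f.index:
        raise ValueError(f"ensemble row {ensemble_name!r} missing from the model table")
    single = f.drop(index=ensemble_name)
    if single.empty:
        raise ValueError("model table needs at least one non-ensemble model")

    def moments(col):
        vals = f[col].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), float(vals.std(ddof=0))

    dist_mean, dist_sd = moments("mean_distance_mm")
    size_mean, size_sd = moments("mean_size_mm3")
    combined = single["gtv_outliers"] + single["edema_outliers"]
    mean_ptv = float(single["ptv_outliers"].mean())
    ens_ptv = int(f.loc[ensemble_name, "ptv_outliers"])
    return SummaryStats(
        total_gtv_edema_outliers=int((f["gtv_outliers"] + f["edema_outliers"]).sum()),
        total_ptv_outliers=int(f["ptv_outliers"].sum()),
        ensemble_ptv_outliers=ens_ptv,
        mean_of_model_mean_distance_mm=dist_mean,
        popsd_of_model_mean_distance_mm=dist_sd,
        mean_of_model_mean_size_mm3=size_mean,
        popsd_of_model_mean_size_mm3=size_sd,
        mean_combined_per_model=float(combined.mean()),
        mean_ptv_per_model=mean_ptv,
        ptv_reduction_percent=100.0 * (mean_ptv - ens_ptv) / mean_ptv if mean_ptv > 0 else 0.0,
    )


def build_volume_table(components) -> tuple[pd.DataFrame, float]:
    """Voxel-vs-mesh volume table with the unweighted mean difference (%).

    Accepts ComponentRecord-like objects (``voxel_volume_mm3`` /
    ``mesh_volume_mm3`` attributes), mappings, or plain (voxel, mesh) pairs.
    """
    rows = []
    for i, comp in enumerate(components):
        if hasattr(comp, "voxel_volume_mm3"):
            voxel, mesh = comp.voxel_volume_mm3, comp.mesh_volume_mm3
            label = getattr(comp, "label", i)
        elif isinstance(comp, dict):
            voxel, mesh = comp["voxel_volume_mm3"], comp["mesh_volume_mm3"]
            label = comp.get("location", i)
        else:
            voxel, mesh = comp
            label = i
        rows.append(
            {
                "location": label,
                "voxel_volume_mm3": voxel,
                "mesh_volume_mm3": mesh,
                "difference_percent": volume_difference_percent(voxel, mesh),
            }
        )
    if not rows:
        raise ValueError("no components to tabulate")
    frame = pd.DataFrame(rows)
    return frame, float(frame["difference_percent"].mean())


@dataclass
class PipelineConfig:
    """Demo-study configuration: 8 phantom cases, 5 models plus the vote,
    on a 72-voxel 2 mm grid."""

    seed: int = 0
    n_cases: int = 8
    grid_shape: tuple[int, int, int] = (72, 72, 72)
    grid_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    ptv_margin_mm: float = 3.0
    prescription_gy: float = 60.0
    falloff_mm: float = 8.0
    connectivity: int = 26
    prediction: dict = field(default_factory=dict)  # PredictionSetConfig overrides
    gamma: dict = field(default_factory=dict)  # GammaCriteria overrides
    run_dosimetry: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic study and (optionally) write its report bundle.

    Stages: phantom cases -> per-model predictions with injected outliers ->
    majority-vote ensemble -> CTV/PTV construction -> per-structure outlier
    inventory -> model table and summary -> dose surrogate on the first case
    with healthy-brain DVH metrics and a gamma comparison of the predicted
    plan against the reference plan.

    Returns a dict with the model table, summary, injection log and
    dosimetry results; with ``out_dir`` it also writes ``model_table.csv``,
    ``injection_log.csv``, ``summary.json`` and ``manifest.json``
    (byte-identical across reruns with the same config and seed).
    """
    grid = GridSpec(config.grid_shape, config.grid_spacing)
    n_models = int(config.prediction.get("n_models", 5))
    model_names = [f"model_{m + 1}" for m in range(n_models)] + [refdata.ENSEMBLE_NAME]
    reports: dict[str, list] = {name: [] for name in model_names}
    logs = []
    names = ("GTV", "edema", "PTV")
    first_case = {}

    def stage(case_id, stage_name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage_name!r} failed on case {case_id}: {exc}") from exc

    for case in range(config.n_cases):
        truth = stage(case, "phantom", make_head_phantom, grid, seed=config.seed * 1009 + case)
        pred_cfg = PredictionSetConfig(
            **{"seed": (config.seed * 9973 + case * 131) % (2**31), **config.prediction}
        )
        preds, log = stage(case, "simulate", simulate_model_predictions, truth, pred_cfg)
        log.insert(0, "case", case)
        logs.append(log)

        fused = stage(case, "vote", vote_per_structure, preds, ["GTV", "edema"])
        fused["brain"] = truth["brain"]
        if "body" in truth:
            fused["body"] = truth["body"]

        for name, pred in zip(model_names, preds + [fused]):
            with_ptv = stage(case, "ptv", build_ptv, pred, config.ptv_margin_mm)
            rep = stage(case, "inventory", outlier_report, with_ptv, names,
                        connectivity=config.connectivity)
            reports[name].append(rep)
            if case == 0 and name == "model_1":
                first_case = {"truth": truth, "prediction": with_ptv}

    table = build_model_table(reports)
    summary = summarize(table)
    injection_log = pd.concat(logs, ignore_index=True) if logs else pd.DataFrame()

    dosimetry = {}
    if config.run_dosimetry and first_case:
        truth = first_case["truth"]
        ref_ptv = build_ptv(truth, config.ptv_margin_mm)["PTV"]
        pred_ptv = first_case["prediction"]["PTV"]
        dose_ref = synthesize_dose(grid, ref_ptv, config.prescription_gy, config.falloff_mm)
        dose_pred = synthesize_dose(grid, pred_ptv, config.prescription_gy, config.falloff_mm)
        hb = healthy_brain(truth["brain"], ref_ptv, grid)
        metrics_ref = dvh_metrics(dose_ref, hb)
        metrics_pred = dvh_metrics(dose_pred, hb)
        gamma = gamma_analysis(dose_ref, dose_pred, GammaCriteria(**config.gamma))
        dosimetry = {
            "healthy_brain_mean_gy_reference": metrics_ref.mean_gy,
            "healthy_brain_mean_gy_predicted": metrics_pred.mean_gy,
            "ptv_d98_gy_reference": dvh_metrics(dose_ref, ref_ptv).d98_gy,
            "ptv_d98_gy_predicted": dvh_metrics(dose_pred, pred_ptv).d98_gy,
            "gamma_pass_rate_percent": gamma.pass_rate_percent,
            "gamma_n_evaluated": gamma.n_evaluated,
        }

    bundle = {
        "model_table": table,
        "summary": summary,
        "injection_log": injection_log,
        "dosimetry": dosimetry,
        "config": config,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "model_table.csv")
        injection_log.to_csv(out_dir / "injection_log.csv", index=False, float_format="%.6g")
        payload = {"summary": summary.to_dict(), "dosimetry": dosimetry}
        (out_dir / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        manifest = {"seed": config.seed, "config_hash": config.config_hash(), "config": asdict(config)}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return bundle
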