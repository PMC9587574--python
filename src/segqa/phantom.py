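"""Synthetic head phantom, controlled outlier experiments, and prediction sets.

Real glioblastoma planning data cannot be redistributed, so every pipeline
stage runs against synthetic inputs generated here:

* a head phantom — nested ellipsoids for body, brain, one main lesion (GTV)
  and its surrounding edema;
* the four controlled outlier experiments (61 scenarios total): 20 outlier
  *locations*, 4 *shapes* at 2 locations, 12 *sizes* at 2 locations, and a
  9-step ladder of the main target's *relative size* (margins -4 ... +4 mm);
* multi-model prediction sets: per model, a perturbed copy of the true
  lesion plus randomly injected disconnected blobs whose count, size and
  distance distributions are configurable, with an injection log so that
  downstream component analysis can be validated against ground truth;
* an analytic dose surrogate — prescription dose inside the PTV with
  exponential falloff in Euclidean distance outside it.

All randomness flows from a single integer seed through a named generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .dosimetry import DoseGrid
from .grid import GridSpec, StructureSet

__all__ = [
    "Scenario",
    "PredictionSetConfig",
    "make_head_phantom",
    "make_blob",
    "generate_experiment_suite",
    "simulate_model_predictions",
    "synthesize_dose",
    "EXPERIMENT3_TARGET_VOLUMES_MM3",
]

# Target voxel volumes (mm^3) for the 12 graded outlier sizes at each of the
# two locations of the size experiment.  Sizes 1-5 are confined to a single
# axial slice; 6-12 span multiple slices.  The D series runs from the
# smallest (4.21 mm^3) to the largest (186.45 mm^3) outlier.
EXPERIMENT3_TARGET_VOLUMES_MM3 = {
    "C": [8.41, 14.02, 30.84, 51.87, 71.50, 12.62, 23.83, 47.66, 88.32, 121.97, 145.80, 148.60],
    "D": [4.21, 12.62, 29.44, 51.87, 67.29, 11.22, 21.02, 51.87, 86.91, 123.36, 123.36, 186.45],
}

_BLOB_SHAPES = ("sphere", "elongated_x", "elongated_y", "elongated_z", "disc_z")
_26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class Scenario:
    """One controlled-experiment setting: a main target plus one outlier."""

    id: str
    experiment: str  # location | shape | size | relative_size
    main_target: np.ndarray
    outlier: np.ndarray
    grid: GridSpec
    params: dict = field(default_factory=dict)


@dataclass
class PredictionSetConfig:
    """Statistical shape of the injected-outlier prediction sets.

    Defaults emulate the outlier statistics observed for deep-learning
    glioblastoma target predictions: a few disconnected false positives per
    structure and distances to the lesion spread over tens of millimetres.
    Sizes are log-normal with median ~140 mm^3 *before* PTV margin growth,
    so that after the 3 mm margin the surviving PTV outliers land near the
    ~1000 mm^3 scale reported for auto-segmented glioblastoma targets.
    """

    n_models: int = 5
    outlier_rate: float = 3.0
    size_log_mean: float = math.log(140.0)
    size_log_sd: float = 1.0
    min_distance_mm: float = 10.0
    max_distance_mm: float = 70.0
    seed: int = 0
    max_size_fraction_of_main: float = 0.25  # outliers stay small vs. the lesion
    max_retries: int = 25

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("need at least one model")
        if self.outlier_rate < 0:
            raise ValueError("outlier rate must be nonnegative")
        if self.min_distance_mm < 0 or self.max_distance_mm < self.min_distance_mm:
            raise ValueError("need 0 <= min_distance_mm <= max_distance_mm")


def _ellipsoid(grid: GridSpec, center_mm, semi_axes_mm) -> np.ndarray:
    coords = [
        (grid.origin[a] + np.arange(grid.shape[a]) * grid.spacing[a] - center_mm[a]) / semi_axes_mm[a]
        for a in range(3)
    ]
    x, y, z = np.meshgrid(*coords, indexing="ij", sparse=True)
    return x * x + y * y + z * z <= 1.0


def make_head_phantom(grid: GridSpec, seed: int = 0) -> StructureSet:
    """Nested-ellipsoid head phantom: body > brain > edema > GTV.

    Ellipsoid extents scale with the grid's physical size; the lesion center
    is jittered by up to 3 mm per axis from a fixed off-center position,
    driven by ``seed``.  No anatomical realism beyond nesting is claimed.
    """
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    center = grid.center_mm()
    rng = np.random.default_rng(seed)

    body_semi = 0.47 * extent
    brain_semi = 0.41 * extent
    gtv_semi = np.array([12.0, 10.0, 9.0])
    edema_semi = gtv_semi + 8.0
    gtv_center = center + np.array([0.15 * extent[0], 0.0, 0.0]) + rng.uniform(-3.0, 3.0, 3)

    if np.any(edema_semi + np.abs(gtv_center - center) >= brain_semi):
        raise ValueError("grid too small to contain the default phantom ellipsoids")

    body = _ellipsoid(grid, center, body_semi)
    brain = _ellipsoid(grid, center, brain_semi)
    gtv = _ellipsoid(grid, gtv_center, gtv_semi)
    edema = np.logical_or(_ellipsoid(grid, gtv_center, edema_semi), gtv)
    if not gtv.any():
        raise ValueError("grid too small: lesion rasterized to an empty mask")
    return StructureSet(grid, {"body": body, "brain": brain, "GTV": gtv, "edema": edema})


def make_blob(grid: GridSpec, center_mm, target_voxel_volume_mm3: float, shape: str = "sphere") -> np.ndarray:
    """Rasterize a compact blob of (at least) the requested voxel volume.

    The blob is the set of the k nearest voxel centers to ``center_mm`` under
    a shape metric, with k = ceil(target / voxel volume) — the smallest voxel
    count whose volume reaches the target.  Ties in distance break by flat
    voxel index, so the result is fully deterministic.

    Shapes: ``sphere`` (Euclidean metric); ``elongated_{x,y,z}`` (metric
    shrunk 3x along the named axis, giving an aspect ratio >= 3);
    ``disc_z`` (confined to the single axial slice nearest the center, for
    outliers that cover one CT slice only).
    """
    if shape not in _BLOB_SHAPES:
        raise ValueError(f"unknown blob shape {shape!r}; choose from {_BLOB_SHAPES}")
    center_mm = np.asarray(center_mm, dtype=float)
    if not grid.contains_point(center_mm):
        raise ValueError(f"blob center {tuple(center_mm)} lies outside the grid")
    voxvol = grid.voxel_volume_mm3
    if target_voxel_volume_mm3 < voxvol:
        raise ValueError(
            f"target volume {target_voxel_volume_mm3} mm^3 is smaller than one voxel ({voxvol} mm^3)"
        )
    k = int(math.ceil(target_voxel_volume_mm3 / voxvol - 1e-9))

    # metric shrunk 4x along the principal axis: the continuous iso-surface
    # has aspect ratio 4, so the discretized blob keeps a ratio >= 3.
    # Elongated blobs are computed with the principal axis swapped into the
    # first position and transposed back, so that equal-volume blobs along
    # different axes are exact axis-swaps of each other on symmetric grids.
    weights = np.ones(3)
    perm = (0, 1, 2)
    if shape.startswith("elongated_"):
        principal = "xyz".index(shape[-1])
        weights[principal] = 1.0 / 4.0
        perm = {0: (0, 1, 2), 1: (1, 0, 2), 2: (2, 1, 0)}[principal]

    mask = grid.empty_mask()
    if shape == "disc_z":
        zi = int(round(grid.world_to_index(center_mm)[2]))
        zi = min(max(zi, 0), grid.shape[2] - 1)
        dx = (grid.origin[0] + np.arange(grid.shape[0]) * grid.spacing[0] - center_mm[0])
        dy = (grid.origin[1] + np.arange(grid.shape[1]) * grid.spacing[1] - center_mm[1])
        d2 = (dx[:, None] ** 2 + dy[None, :] ** 2).ravel()
        if k > d2.size:
            raise ValueError("target volume exceeds the single-slice capacity")
        pick = np.lexsort((np.arange(d2.size), d2))[:k]
        plane = np.zeros(d2.size, dtype=bool)
        plane[pick] = True
        mask[:, :, zi] = plane.reshape(grid.shape[:2])
        return mask

    axes = [
        (grid.origin[a] + np.arange(grid.shape[a]) * grid.spacing[a] - center_mm[a]) * weights[a]
        for a in perm
    ]
    x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
    d2 = (x * x + y * y + z * z).ravel()
    if k > d2.size:
        raise ValueError("target volume exceeds the grid capacity")
    pick = np.lexsort((np.arange(d2.size), d2))[:k]
    flat = np.zeros(d2.size, dtype=bool)
    flat[pick] = True
    canonical = flat.reshape(tuple(grid.shape[a] for a in perm))
    return np.transpose(canonical, perm)  # each swap is its own inverse


def _surface_distance_along(mask: np.ndarray, grid: GridSpec, start_mm, direction) -> float:
    """Distance (mm) from ``start_mm`` to the mask boundary along a ray."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    step = 0.25 * min(grid.spacing)
    t = 0.0
    limit = float(np.linalg.norm(np.asarray(grid.shape) * np.asarray(grid.spacing)))
    while t < limit:
        p = np.asarray(start_mm) + t * direction
        if not grid.contains_point(p):
            return t
        idx = tuple(np.round(grid.world_to_index(p)).astype(int))
        if not mask[idx]:
            return t
        t += step
    return t


def _is_detached(blob: np.ndarray, forbidden: np.ndarray) -> bool:
    """True if the blob avoids the (already dilated) exclusion mask."""
    return not np.logical_and(blob, forbidden).any()


def _check_scenarios(scenarios: list[Scenario]) -> list[str]:
    bad = []
    grown_cache: dict[int, np.ndarray] = {}
    for sc in scenarios:
        if not sc.outlier.any():
            bad.append(sc.id)
            continue
        key = id(sc.main_target)
        if key not in grown_cache:
            grown_cache[key] = ndimage.binary_dilation(sc.main_target, structure=_26)
        if np.logical_and(grown_cache[key], sc.outlier).any():
            bad.append(sc.id)
    return bad


def generate_experiment_suite(grid: GridSpec, base: StructureSet, config: dict | None = None) -> list[Scenario]:
    """Build the 61 controlled outlier scenarios around a reference target.

    Partition: 20 location scenarios (equal-volume spheres stepped outward
    along +-x, +-y and +z from the target), 4 shapes x 2 locations = 8 shape
    scenarios, 12 sizes x 2 locations = 24 size scenarios (graded target
    volumes, the first five on a single axial slice), and 9 relative-size
    scenarios (the main target eroded/dilated by -4 ... +4 mm against one
    fixed small outlier).
    """
    from .targets import build_ptv, expand_margin  # local import to avoid a cycle

    cfg = {
        "location_volume_mm3": 13.0,
        "location_distances_mm": (10.0, 20.0, 30.0, 40.0),
        "shape_volume_mm3": 60.0,
        "shape_offset_mm": 25.0,
        "size_offsets": {"C": ("-y", 35.0), "D": ("+x", 12.0)},
        "relative_margins_mm": tuple(range(-4, 5)),
        "relative_outlier": ("D", 2),  # series and 1-based size index
        "ptv_margin_mm": 3.0,
    }
    if config:
        cfg.update(config)

    if "PTV" in base:
        target = base["PTV"]
    else:
        target = build_ptv(base, cfg["ptv_margin_mm"])["PTV"]
    if not target.any():
        raise ValueError("base structure set has an empty main target")
    centroid = grid.index_to_world(ndimage.center_of_mass(target))

    directions = {"+x": (1, 0, 0), "-x": (-1, 0, 0), "+y": (0, 1, 0), "-y": (0, -1, 0), "+z": (0, 0, 1)}

    def offset_center(dir_name: str, surface_offset_mm: float) -> np.ndarray:
        d = np.asarray(directions[dir_name], float)
        r = _surface_distance_along(target, grid, centroid, d)
        return centroid + (r + surface_offset_mm) * d

    scenarios: list[Scenario] = []
    failed: list[str] = []

    def blob_or_none(scenario_id: str, center, volume: float, shape: str):
        try:
            return make_blob(grid, center, volume, shape)
        except ValueError:
            failed.append(scenario_id)
            return None

    # Experiment 1 - location: equal-volume spheres stepped along five rays.
    loc_index = 0
    for dir_name in ("+x", "-x", "+y", "-y", "+z"):
        for dist in cfg["location_distances_mm"]:
            loc_index += 1
            center = offset_center(dir_name, dist)
            blob = blob_or_none(f"loc_{loc_index:02d}", center, cfg["location_volume_mm3"], "sphere")
            if blob is None:
                continue
            scenarios.append(
                Scenario(
                    id=f"loc_{loc_index:02d}",
                    experiment="location",
                    main_target=target,
                    outlier=blob,
                    grid=grid,
                    params={"location_index": loc_index, "direction": dir_name,
                            "surface_distance_mm": dist,
                            "target_voxel_volume_mm3": cfg["location_volume_mm3"]},
                )
            )

    # Experiment 2 - shape: equal-volume blobs of 4 shapes at locations A and B.
    shape_names = ("sphere", "elongated_x", "elongated_y", "elongated_z")
    center_a = offset_center("-x", cfg["shape_offset_mm"])
    center_b = center_a + np.array([0.0, 0.0, 0.30 * grid.shape[2] * grid.spacing[2] * 0.5])
    for loc_name, center in (("A", center_a), ("B", center_b)):
        for si, shape in enumerate(shape_names, start=1):
            blob = blob_or_none(f"shape_{loc_name}{si}", center, cfg["shape_volume_mm3"], shape)
            if blob is None:
                continue
            scenarios.append(
                Scenario(
                    id=f"shape_{loc_name}{si}",
                    experiment="shape",
                    main_target=target,
                    outlier=blob,
                    grid=grid,
                    params={"shape_index": si, "shape": shape, "location": loc_name,
                            "target_voxel_volume_mm3": cfg["shape_volume_mm3"]},
                )
            )

    # Experiment 3 - size: 12 graded volumes at locations C and D;
    # sizes 1-5 cover a single axial slice, 6-12 span multiple slices.
    exp3_centers = {}
    for series, (dir_name, offset) in cfg["size_offsets"].items():
        exp3_centers[series] = offset_center(dir_name, offset)
    for series in ("C", "D"):
        center = exp3_centers[series]
        for si, vol in enumerate(EXPERIMENT3_TARGET_VOLUMES_MM3[series], start=1):
            shape = "disc_z" if si <= 5 else "sphere"
            blob = blob_or_none(f"size_{series}{si}", center, vol, shape)
            if blob is None:
                continue
            scenarios.append(
                Scenario(
                    id=f"size_{series}{si}",
                    experiment="size",
                    main_target=target,
                    outlier=blob,
                    grid=grid,
                    params={"size_index": si, "location": series, "single_slice": si <= 5,
                            "target_voxel_volume_mm3": vol},
                )
            )

    # Experiment 4 - relative size: margin ladder on the main target against
    # one fixed small outlier.
    rel_series, rel_idx = cfg["relative_outlier"]
    rel_vol = EXPERIMENT3_TARGET_VOLUMES_MM3[rel_series][rel_idx - 1]
    rel_shape = "disc_z" if rel_idx <= 5 else "sphere"
    rel_blob = blob_or_none("rel", exp3_centers[rel_series], rel_vol, rel_shape)
    if rel_blob is None:
        raise ValueError("relative-size outlier could not be placed on this grid")
    for margin in cfg["relative_margins_mm"]:
        resized = expand_margin(target, grid, float(margin))
        scenarios.append(
            Scenario(
                id=f"rel_{margin:+d}mm",
                experiment="relative_size",
                main_target=resized,
                outlier=rel_blob,
                grid=grid,
                params={"ptv_margin_offset_mm": float(margin),
                        "target_voxel_volume_mm3": rel_vol,
                        "outlier": f"{rel_series}{rel_idx}"},
            )
        )

    failed.extend(_check_scenarios(scenarios))
    if failed:
        raise ValueError(
            "brain/grid too small to host the requested outlier placements; "
            f"failed scenarios: {', '.join(failed)}"
        )
    return scenarios


def simulate_model_predictions(
    truth: StructureSet, config: PredictionSetConfig
) -> tuple[list[StructureSet], pd.DataFrame]:
    """Emulate per-model auto-segmentations with injected disconnected outliers.

    Each model's GTV and edema are the true masks shifted by up to one voxel
    (the systematic part of model disagreement) plus ``N ~ Poisson(rate)``
    spherical blobs with log-normal sizes, centered inside the brain at a
    distance drawn uniformly from ``[min, max]`` mm to the main structure.
    Every injected blob is kept disconnected (26-connectivity) from the main
    structure and from the other blobs; placements that fail after bounded
    retries are logged as dropped, never silently ignored.

    Returns the per-model structure sets and the injection log with one row
    per injected (or dropped) outlier: model, structure, outlier id, exact
    voxel volume, and the closest center-to-center distance to the main
    structure.
    """
    truth.require("GTV", "edema", "brain")
    grid = truth.grid
    rng = np.random.default_rng(config.seed)
    brain = truth["brain"]
    voxvol = grid.voxel_volume_mm3

    predictions: list[StructureSet] = []
    log_rows: list[dict] = []
    for m in range(config.n_models):
        pred = StructureSet(grid)
        if "body" in truth:
            pred["body"] = truth["body"].copy()
        pred["brain"] = brain.copy()
        for structure in ("GTV", "edema"):
            shift = rng.integers(-1, 2, size=3)
            main = ndimage.shift(truth[structure].astype(np.uint8), shift, order=0, cval=0).astype(bool)
            if not main.any():
                main = truth[structure].copy()

            dist_to_main = ndimage.distance_transform_edt(~main, sampling=grid.spacing)
            candidates = np.logical_and(brain, ~main)
            candidates &= dist_to_main >= config.min_distance_mm
            candidates &= dist_to_main <= config.max_distance_mm
            cand_idx = np.argwhere(candidates)
            cand_dist = dist_to_main[candidates]

            forbidden = ndimage.binary_dilation(main, structure=_26)
            combined = main.copy()
            n_outliers = rng.poisson(config.outlier_rate)
            main_volume = float(main.sum()) * voxvol
            for oid in range(1, int(n_outliers) + 1):
                size = float(np.exp(rng.normal(config.size_log_mean, config.size_log_sd)))
                size = min(max(size, voxvol), config.max_size_fraction_of_main * main_volume)
                placed = False
                for _ in range(config.max_retries):
                    if cand_idx.size == 0:
                        break
                    u = rng.uniform(config.min_distance_mm, config.max_distance_mm)
                    near = np.abs(cand_dist - u) <= grid.voxel_diagonal_mm
                    pool = np.flatnonzero(near) if near.any() else np.arange(cand_dist.size)
                    center = grid.index_to_world(cand_idx[rng.choice(pool)])
                    blob = make_blob(grid, center, size, "sphere")
                    if _is_detached(blob, forbidden):
                        combined |= blob
                        forbidden |= ndimage.binary_dilation(blob, structure=_26)
                        log_rows.append(
                            {
                                "model": m + 1,
                                "structure": structure,
                                "outlier_id": oid,
                                "voxel_volume_mm3": float(blob.sum()) * voxvol,
                                "distance_mm": float(dist_to_main[blob].min()),
                                "dropped": False,
                            }
                        )
                        placed = True
                        break
                if not placed:
                    log_rows.append(
                        {
                            "model": m + 1,
                            "structure": structure,
                            "outlier_id": oid,
                            "voxel_volume_mm3": float("nan"),
                            "distance_mm": float("nan"),
                            "dropped": True,
                        }
                    )
            pred[structure] = combined
        predictions.append(pred)

    log = pd.DataFrame(
        log_rows,
        columns=["model", "structure", "outlier_id", "voxel_volume_mm3", "distance_mm", "dropped"],
    )
    return predictions, log


def synthesize_dose(
    grid: GridSpec, ptv: np.ndarray, prescription_gy: float = 60.0, falloff_mm: float = 8.0
) -> DoseGrid:
    """Analytic dose surrogate: prescription inside the PTV, exponential
    falloff ``prescription * exp(-d / falloff)`` with Euclidean distance d
    (mm) outside.  By construction the median PTV dose equals the
    prescription (100% of the prescribed dose covers 50% of the PTV), dose is
    positive everywhere, and strictly decreases along any ray leaving the
    PTV.  Only this monotone distance dependence — more target volume means
    more dose to surrounding tissue — is meant to carry over from a real
    optimizer."""
    ptv = grid.validate_mask(ptv)
    if not ptv.any():
        raise ValueError("PTV is empty")
    if prescription_gy <= 0 or falloff_mm <= 0:
        raise ValueError("prescription and falloff must be positive")
    dist = ndimage.distance_transform_edt(~ptv, sampling=grid.spacing)
    dose = prescription_gy * np.exp(-dist / falloff_mm)
    return DoseGrid(grid, dose, prescription_gy)
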