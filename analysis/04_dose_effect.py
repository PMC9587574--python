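"""Dose effect of a disconnected PTV outlier under the analytic surrogate.

Synthesizes a reference plan and a plan whose PTV carries a distant
disconnected outlier, and compares healthy-brain DVH metrics and the
3%/3mm gamma pass rate between the two.  The direction of the effect —
outliers pull dose into healthy brain — is the reproduction target; the
absolute numbers belong to the surrogate, not to a clinical optimizer.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from segqa import (
    GridSpec,
    cumulative_dvh,
    dvh_metrics,
    gamma_analysis,
    healthy_brain,
    make_head_phantom,
    synthesize_dose,
)
from segqa.targets import build_ptv


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    grid = GridSpec((64, 64, 64), (2.0, 2.0, 2.0))
    truth = make_head_phantom(grid, seed=args.seed)
    ref_ptv = build_ptv(truth, 3.0)["PTV"]
    outlier = grid.empty_mask()
    outlier[12:16, 30:34, 30:34] = True

    dose_ref = synthesize_dose(grid, ref_ptv)
    dose_out = synthesize_dose(grid, ref_ptv | outlier)
    hb = healthy_brain(truth["brain"], ref_ptv, grid)

    curves = []
    for label, dose in (("reference", dose_ref), ("with_outlier", dose_out)):
        curve = cumulative_dvh(dose, hb, name=f"healthy_brain_{label}")
        curves.append(
            pd.DataFrame(
                {"plan": label, "dose_gy": curve.bin_edges_gy,
                 "volume_percent": curve.cumulative_volume_percent}
            )
        )
    pd.concat(curves).to_csv(args.out / "healthy_brain_dvh.csv", index=False, float_format="%.4f")

    m_ref = dvh_metrics(dose_ref, hb)
    m_out = dvh_metrics(dose_out, hb)
    gamma = gamma_analysis(dose_ref, dose_out)
    summary = {
        "healthy_brain_mean_gy": {"reference": m_ref.mean_gy, "with_outlier": m_out.mean_gy},
        "healthy_brain_d1cc_gy": {"reference": m_ref.d1cc_gy, "with_outlier": m_out.d1cc_gy},
        "gamma_pass_rate_percent": gamma.pass_rate_percent,
        "gamma_n_evaluated": gamma.n_evaluated,
    }
    (args.out / "dose_effect.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))
    print(
        "outlier increases healthy-brain mean dose by "
        f"{m_out.mean_gy - m_ref.mean_gy:.3f} Gy under the surrogate"
    )


if __name__ == "__main__":
    main()
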