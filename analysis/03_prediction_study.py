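"""Simulated multi-model prediction study with injected outliers.

Runs the demo pipeline: phantom cases, five simulated model predictions per
case with randomly injected disconnected outliers, the majority-vote
ensemble, CTV/PTV construction, per-structure outlier inventory, and a
dosimetry check on the first case.  Writes the model table, injection log
and summary bundle, and prints the headline numbers.
"""

import argparse
import json
from pathlib import Path

from segqa import PipelineConfig, run_pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--cases", type=int, default=8)
    parser.add_argument("--out", type=Path, default=Path("results/prediction_study"))
    args = parser.parse_args()

    bundle = run_pipeline(PipelineConfig(seed=args.seed, n_cases=args.cases), out_dir=args.out)
    s = bundle["summary"]
    print(f"report bundle written to {args.out}")
    print(bundle["model_table"].frame.to_string(float_format=lambda v: f"{v:.1f}"))
    print(
        f"raw GTV+edema outliers: {s.total_gtv_edema_outliers}; "
        f"after PTV: {s.total_ptv_outliers}; "
        f"ensemble PTV outliers: {s.ensemble_ptv_outliers} "
        f"({s.ptv_reduction_percent:.1f}% reduction vs single-model mean)"
    )
    if bundle["dosimetry"]:
        print("dosimetry (case 0):", json.dumps(bundle["dosimetry"], indent=2))


if __name__ == "__main__":
    main()
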