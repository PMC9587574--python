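# segqa — false-positive outliers in auto-segmented radiotherapy targets

Deep-learning models that segment glioblastoma targets (gross tumor volume,
GTV, and peritumoral edema) occasionally produce *random false positives*:
small regions disconnected from the main lesion. If such a region is carried
through clinical target construction — CTV = GTV ∪ edema, PTV = CTV grown by
a 3 mm isotropic margin — the treatment-plan optimizer will dutifully direct
dose at it, at the cost of healthy brain tissue.

`segqa` is an analysis pipeline that quantifies this failure mode:

- **components** — decompose a binary mask into its *main structure* (the
  largest connected region, 26-connectivity by default) and *outliers*
  (every other region), measuring each outlier's voxel volume
  (count × voxel size), mesh volume (volume enclosed by the 0.5-level
  isosurface of the occupancy field), and closest spacing-aware
  center-to-center distance to the main structure.
- **targets** — CTV/PTV construction with exact Euclidean margin growth on
  anisotropic grids (negative margins erode), Dice similarity, and
  per-structure outlier reports.
- **ensemble** — voxelwise majority-vote fusion of multiple models
  (strict majority, 3-of-5 by default).
- **dosimetry** — an evaluation layer for any dose grid: plan normalization
  (D50% of PTV = prescription), cumulative DVHs, coverage metrics (mean,
  min, max, D95%, D98%, D1%, D1cc), the healthy-brain structure
  (brain ∖ PTV), and 3D gamma analysis (3% of prescription / 3 mm,
  20 Gy cutoff).
- **phantom** — synthetic generators so everything runs without patient
  data: a nested-ellipsoid head phantom, the 61 controlled outlier
  scenarios (20 locations / 4 shapes × 2 / 12 sizes × 2 / 9 relative target
  sizes), multi-model prediction sets with logged injected outliers, and an
  analytic exponential-falloff dose surrogate.
- **reporting** — aggregation into a per-model table and summary statistics
  (totals before/after PTV, pooled outlier size/distance moments, the
  ensemble's PTV-outlier reduction), plus the end-to-end `run_pipeline`.

## Worked example

```python
import numpy as np
from segqa import (GridSpec, make_head_phantom, simulate_model_predictions,
                   PredictionSetConfig, outlier_report)
from segqa.targets import build_ptv

grid = GridSpec((64, 64, 64), spacing=(2.0, 2.0, 2.0))
truth = make_head_phantom(grid, seed=3)
preds, log = simulate_model_predictions(truth, PredictionSetConfig(seed=7))

pred = build_ptv(preds[0], margin_mm=3.0)      # adds CTV and PTV
report = outlier_report(pred, ["GTV", "edema", "PTV"])
print({name: dec.n_outliers for name, dec in report.items()})
for o in report["PTV"].outliers[:2]:
    print(f"outlier: {o.voxel_volume_mm3:.0f} mm^3, "
          f"{o.distance_to_main_mm:.1f} mm from the main target")
```

prints

```
{'GTV': 3, 'edema': 6, 'PTV': 9}
outlier: 584 mm^3, 37.6 mm from the main target
outlier: 744 mm^3, 40.3 mm from the main target
```

— model 1's GTV prediction carries 3 disconnected false positives and its
edema 6; after margin growth all 9 persist as disconnected PTV components,
each inventoried with its size and its closest distance to the lesion.
The `log` returned by the simulator records what was actually injected, so
the inventory can be validated against ground truth.

The numbered scripts under `analysis/` run the full studies and write their
tables under `results/`: the 61-scenario controlled-experiment inventory
(`01`), the voxel-vs-mesh volume table and its size trend (`02`), the
multi-model prediction study with majority voting (`03`), the dose effect
of a PTV outlier under the surrogate (`04`), and the aggregation of the
published six-model outlier inventory (`05`).

## Scope

The package deliberately contains no treatment-planning optimizer: clinical
plan quality numbers (real D98% deviations, gamma improvements between
optimized plans) depend on a commercial TPS and are out of scope. The dose
surrogate reproduces direction, not magnitude, of dosimetric effects.
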