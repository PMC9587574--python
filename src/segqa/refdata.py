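"""Published benchmark inventories used as aggregation inputs.

Two small tables from a published glioblastoma auto-segmentation QA study
accompany the package as reference inputs:

* ``MODEL_OUTLIER_COUNTS`` — raw outlier counts per structure (GTV, edema,
  and the 3 mm-margin PTV) over 20 test cases for five cross-validation
  models of one architecture plus their majority-vote ensemble, with the
  pooled mean/median size and closest distance of each model's PTV outliers.
* ``VOLUME_PAIRS`` — voxel volume vs. mesh volume (mm^3) of the 24 graded
  outliers of the size experiment (series C and D, 12 sizes each; rows D10
  and D11 are identical as printed), together with the published relative
  difference for cross-checking.

These numbers are *inputs* to :mod:`segqa.reporting`; the package recomputes
every aggregate from them.
"""

from __future__ import annotations

import pandas as pd

MODEL_NAMES = ["model_1", "model_2", "model_3", "model_4", "model_5", "majority_vote"]
ENSEMBLE_NAME = "majority_vote"

MODEL_OUTLIER_COUNTS = pd.DataFrame(
    {
        "gtv_outliers": [56, 61, 47, 53, 64, 209],
        "edema_outliers": [243, 201, 259, 208, 214, 272],
        "ptv_outliers": [17, 18, 36, 22, 28, 16],
        "mean_distance_mm": [37.5, 33.2, 39.0, 35.6, 48.9, 36.6],
        "median_distance_mm": [33.0, 27.9, 39.6, 38.4, 45.4, 41.5],
        "mean_size_mm3": [923.3, 1150.1, 1029.2, 1053.1, 856.4, 1052.9],
        "median_size_mm3": [636.0, 554.0, 690.0, 577.0, 483.0, 477.0],
    },
    index=pd.Index(MODEL_NAMES, name="model"),
)

# location, voxel volume (mm^3), mesh volume (mm^3), published difference (%)
VOLUME_PAIRS = pd.DataFrame(
    [
        ("C1", 8.41, 5.49, 34.72),
        ("C2", 14.02, 10.05, 28.32),
        ("C3", 30.84, 25.12, 18.55),
        ("C4", 51.87, 45.09, 13.07),
        ("C5", 71.50, 63.31, 11.45),
        ("C6", 12.62, 9.11, 27.81),
        ("C7", 23.83, 19.04, 20.10),
        ("C8", 47.66, 41.65, 12.61),
        ("C9", 88.32, 80.72, 8.61),
        ("C10", 121.97, 113.20, 7.19),
        ("C11", 145.80, 136.45, 6.41),
        ("C12", 148.60, 139.02, 6.45),
        ("D1", 4.21, 1.98, 52.97),
        ("D2", 12.62, 8.65, 31.46),
        ("D3", 29.44, 24.07, 18.24),
        ("D4", 51.87, 45.09, 13.07),
        ("D5", 67.29, 59.11, 12.16),
        ("D6", 11.22, 7.94, 29.23),
        ("D7", 21.02, 16.71, 20.50),
        ("D8", 51.87, 46.15, 11.03),
        ("D9", 86.91, 79.85, 8.12),
        ("D10", 123.36, 114.61, 7.09),
        ("D11", 123.36, 114.61, 7.09),
        ("D12", 186.45, 176.17, 5.51),
    ],
    columns=["location", "voxel_volume_mm3", "mesh_volume_mm3", "published_difference_percent"],
)
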