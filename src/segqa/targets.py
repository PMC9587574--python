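"""Target-volume construction: CTV, margin growth to PTV, mask similarity.

The clinical target volume (CTV) is the union of the gross tumor volume and
the peritumoral edema; the planning target volume (PTV) adds an isotropic
geometric safety margin (3 mm by default, per RTOG-style glioblastoma
planning).  Margins are applied by thresholding a spacing-aware Euclidean
distance transform rather than by structuring-element dilation, so they are
exact on anisotropic grids (e.g. 1 x 1 x 3 mm CT); a negative margin erodes,
defined symmetrically on the mask complement.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .components import decompose
from .grid import GridSpec, StructureSet

__all__ = ["build_ctv", "expand_margin", "build_ptv", "dsc", "outlier_report", "OutlierReport"]


def build_ctv(gtv: np.ndarray, edema: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Clinical target volume: voxelwise union of GTV and edema."""
    return np.logical_or(grid.validate_mask(gtv), grid.validate_mask(edema))


def expand_margin(mask: np.ndarray, grid: GridSpec, margin_mm: float) -> np.ndarray:
    """Grow (or, for negative margins, shrink) a mask by a Euclidean margin.

    A voxel is included iff its center lies within ``margin_mm`` (spacing-aware
    Euclidean distance) of some occupied voxel center.  Margin 0 is the
    identity; a negative margin keeps only voxels farther than ``|margin|``
    from the mask complement (erosion).
    """
    mask = grid.validate_mask(mask)
    if margin_mm == 0:
        return mask.copy()
    if not mask.any():
        return mask.copy()
    if margin_mm > 0:
        dist = ndimage.distance_transform_edt(~mask, sampling=grid.spacing)
        return dist <= margin_mm
    if mask.all():
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask, sampling=grid.spacing)
    return dist > -margin_mm


def build_ptv(structures: StructureSet, margin_mm: float = 3.0, clip_to_body: bool = True) -> StructureSet:
    """Add CTV (= GTV union edema) and PTV (= CTV + margin) to a structure set.

    The PTV is clipped to the body contour when one is present — never to the
    brain, because disconnected false positives can sit outside brain tissue
    and must survive into the PTV inventory.
    """
    structures.require("GTV", "edema")
    out = structures.copy()
    ctv = build_ctv(out["GTV"], out["edema"], out.grid)
    ptv = expand_margin(ctv, out.grid, margin_mm)
    if clip_to_body and "body" in out:
        ptv = np.logical_and(ptv, out["body"])
    out["CTV"] = ctv
    out["PTV"] = ptv
    return out


def dsc(a: np.ndarray, b: np.ndarray, grid: GridSpec) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|); 1.0 if both empty."""
    a = grid.validate_mask(a)
    b = grid.validate_mask(b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


class OutlierReport(dict):
    """structure name -> Decomposition, with flat-table serialization."""

    def counts(self) -> dict[str, int]:
        return {name: d.n_outliers for name, d in self.items()}

    def to_records(self, **context) -> list[dict]:
        rows = []
        for name, d in self.items():
            for rec in [d.main, *d.outliers]:
                rows.append(
                    {
                        **context,
                        "structure": name,
                        "label": rec.label,
                        "is_main": rec.is_main,
                        "voxel_count": rec.voxel_count,
                        "voxel_volume_mm3": rec.voxel_volume_mm3,
                        "mesh_volume_mm3": rec.mesh_volume_mm3,
                        "distance_mm": rec.distance_to_main_mm,
                    }
                )
        return rows


def outlier_report(
    structures: StructureSet,
    structure_names,
    connectivity: int = 26,
    with_mesh: bool = False,
) -> OutlierReport:
    """Per-structure outlier inventory (count, size, closest distance)."""
    structures.require(*structure_names)
    ref = None
    if "brain" in structures and structures["brain"].any():
        ref = structures.grid.index_to_world(ndimage.center_of_mass(structures["brain"]))
    report = OutlierReport()
    for name in structure_names:
        report[name] = decompose(
            structures[name], structures.grid, connectivity=connectivity,
            ref_point_mm=ref, with_mesh=with_mesh,
        )
    return report
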