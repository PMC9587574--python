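"""Dose-grid surrogate analysis: normalization, DVH metrics, gamma comparison.

The package carries no treatment-planning optimizer; dose distributions come
from the analytic surrogate in :mod:`segqa.phantom` or from files.  This
module implements the plan-evaluation layer on top of any dose grid:

* plan normalization so that 100% of the prescription covers 50% of the PTV
  (D50% = prescription);
* cumulative dose-volume histograms and the standard coverage metrics
  (mean/min/max, D95%, D98%, D1%, D1cc);
* the healthy-brain structure (brain minus PTV) used as the normal-tissue
  dose burden surrogate;
* 3D gamma analysis with global dose normalization (percent of prescription),
  distance-to-agreement in mm, and a low-dose cutoff applied to the reference
  grid.

Dx% ("dose received by at least x% of the volume") is the linearly
interpolated empirical quantile of the voxel doses at level 1 - x/100;
DVcc interpolates the sorted doses at the fractional hottest-n-voxels index.
Dmin/Dmax are raw voxel extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import GridSpec

__all__ = [
    "DoseGrid",
    "DVHCurve",
    "DVHMetrics",
    "GammaCriteria",
    "GammaResult",
    "normalize_plan",
    "cumulative_dvh",
    "dvh_metrics",
    "healthy_brain",
    "gamma_analysis",
]


@dataclass
class DoseGrid:
    """A nonnegative dose array (Gy) on a voxel lattice, with its prescription.

    Default prescription is 60 Gy (30 fractions of 2 Gy, the standard
    glioblastoma schedule).
    """

    grid: GridSpec
    dose: np.ndarray
    prescription_gy: float = 60.0

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.shape:
            raise ValueError(f"dose shape {self.dose.shape} does not match grid {self.grid.shape}")
        if (self.dose < 0).any():
            raise ValueError("dose must be nonnegative everywhere")
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")


@dataclass
class DVHCurve:
    structure: str
    bin_edges_gy: np.ndarray
    cumulative_volume_percent: np.ndarray
    voxel_doses: np.ndarray  # sorted ascending; retained for exact percentiles


@dataclass
class DVHMetrics:
    mean_gy: float
    min_gy: float
    max_gy: float
    d95_gy: float
    d98_gy: float
    d1percent_gy: float
    d1cc_gy: float
    d1cc_warning: bool = False  # structure smaller than 1 cc; d1cc = min dose


@dataclass
class GammaCriteria:
    """3%/3mm with a 20 Gy cutoff by default; dose tolerance is global
    (percent of the prescription, not of local dose)."""

    dose_percent: float = 3.0
    dta_mm: float = 3.0
    cutoff_gy: float = 20.0

    def __post_init__(self) -> None:
        if self.dose_percent <= 0 or self.dta_mm <= 0 or self.cutoff_gy <= 0:
            raise ValueError("all gamma criteria must be positive")


@dataclass
class GammaResult:
    gamma_map: np.ndarray  # NaN where not evaluated (below cutoff)
    pass_rate_percent: float
    n_evaluated: int
    criteria: GammaCriteria = field(default_factory=GammaCriteria)


def normalize_plan(dose: DoseGrid, ptv: np.ndarray) -> DoseGrid:
    """Scale the dose so the median dose inside the PTV equals the prescription."""
    ptv = dose.grid.validate_mask(ptv)
    if not ptv.any():
        raise ValueError("PTV is empty")
    median = float(np.median(dose.dose[ptv]))
    if median <= 0:
        raise ValueError("median PTV dose is zero; cannot normalize")
    scale = dose.prescription_gy / median
    return DoseGrid(dose.grid, dose.dose * scale, dose.prescription_gy)


def cumulative_dvh(dose: DoseGrid, structure: np.ndarray, name: str = "", bin_gy: float = 0.1) -> DVHCurve:
    """Cumulative DVH: volume% receiving at least each bin-edge dose."""
    structure = dose.grid.validate_mask(structure)
    if not structure.any():
        raise ValueError("structure is empty")
    doses = np.sort(dose.dose[structure])
    edges = np.arange(0.0, doses[-1] + 2 * bin_gy, bin_gy)
    # volume receiving >= D, by binary search in the sorted sample
    n_below = np.searchsorted(doses, edges, side="left")
    volume = 100.0 * (doses.size - n_below) / doses.size
    return DVHCurve(name, edges, volume, doses)


def _dose_at_percent(doses_sorted: np.ndarray, percent: float) -> float:
    """Dx%: largest dose received by at least ``percent`` % of the volume."""
    return float(np.quantile(doses_sorted, 1.0 - percent / 100.0))


def _dose_at_volume_mm3(doses_sorted: np.ndarray, volume_mm3: float, voxel_volume_mm3: float) -> float:
    """DVcc: dose of the (fractional) n-th hottest voxel, n = volume / voxel size."""
    n = volume_mm3 / voxel_volume_mm3
    desc = doses_sorted[::-1]
    idx = min(max(n - 1.0, 0.0), desc.size - 1)
    return float(np.interp(idx, np.arange(desc.size), desc))


def dvh_metrics(dose: DoseGrid, structure: np.ndarray) -> DVHMetrics:
    """Coverage/hot-spot metrics of one structure under one dose grid."""
    structure = dose.grid.validate_mask(structure)
    if not structure.any():
        raise ValueError("structure is empty")
    doses = np.sort(dose.dose[structure])
    voxvol = dose.grid.voxel_volume_mm3
    struct_mm3 = doses.size * voxvol
    if struct_mm3 < 1000.0:
        d1cc, warn = float(doses[0]), True
    else:
        d1cc, warn = _dose_at_volume_mm3(doses, 1000.0, voxvol), False
    return DVHMetrics(
        mean_gy=float(doses.mean()),
        min_gy=float(doses[0]),
        max_gy=float(doses[-1]),
        d95_gy=_dose_at_percent(doses, 95.0),
        d98_gy=_dose_at_percent(doses, 98.0),
        d1percent_gy=_dose_at_percent(doses, 1.0),
        d1cc_gy=d1cc,
        d1cc_warning=warn,
    )


def healthy_brain(brain: np.ndarray, ptv: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Brain minus PTV: the normal-tissue dose-burden surrogate."""
    return np.logical_and(grid.validate_mask(brain), ~grid.validate_mask(ptv))


def _fine_grid(dose: np.ndarray, factor: int) -> np.ndarray:
    """Trilinear subdivision: fine index f*i coincides with coarse voxel i."""
    if factor == 1:
        return np.asarray(dose, dtype=float)
    fine_shape = [factor * (n - 1) + 1 for n in dose.shape]
    axes = [np.arange(m) / factor for m in fine_shape]
    coords = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(np.asarray(dose, dtype=float), coords, order=1, mode="nearest")


def gamma_analysis(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: GammaCriteria = None,
    subdivision: int = 3,
    search_radius_factor: float | None = 3.0,
) -> GammaResult:
    """3D global gamma index of ``evaluated`` against ``reference``.

    For each reference voxel at or above the cutoff,

        gamma = min over fine evaluated positions r of
                sqrt((|dr| / dta)^2 + (dD / (p/100 * prescription))^2),

    where the evaluated dose is trilinearly interpolated on a lattice
    subdivided ``subdivision`` times per voxel.  The search is truncated at
    ``search_radius_factor * dta`` mm (candidate offsets are visited in order
    of increasing distance with an early exit, so truncation rarely binds);
    pass ``search_radius_factor=None`` for the exhaustive search over the
    whole grid.
    """
    if criteria is None:
        criteria = GammaCriteria()
    if reference.grid != evaluated.grid:
        raise ValueError("reference and evaluated dose grids must match")
    grid = reference.grid
    tol_gy = criteria.dose_percent / 100.0 * reference.prescription_gy
    ref_mask = reference.dose >= criteria.cutoff_gy
    n_eval = int(ref_mask.sum())
    if n_eval == 0:
        raise ValueError(f"no reference voxel at or above the {criteria.cutoff_gy} Gy cutoff")

    f = int(subdivision)
    fine = _fine_grid(evaluated.dose, f)
    fine_shape = np.array(fine.shape)
    fine_spacing = np.asarray(grid.spacing) / f

    idx = np.argwhere(ref_mask)
    ref_fine = idx * f  # reference voxel centers on the fine lattice
    dref = reference.dose[ref_mask]

    if search_radius_factor is None:
        max_off = fine_shape - 1  # reach every fine point from any voxel
    else:
        radius = search_radius_factor * criteria.dta_mm
        max_off = np.minimum(np.ceil(radius / fine_spacing).astype(int), fine_shape - 1)

    offs = np.stack(
        np.meshgrid(*[np.arange(-m, m + 1) for m in max_off], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    d2_mm = np.einsum("ij,ij->i", offs * fine_spacing, offs * fine_spacing)
    if search_radius_factor is not None:
        keep = d2_mm <= (search_radius_factor * criteria.dta_mm) ** 2
        offs, d2_mm = offs[keep], d2_mm[keep]
    order = np.argsort(d2_mm, kind="stable")
    offs, d2_mm = offs[order], d2_mm[order]
    space2 = d2_mm / criteria.dta_mm**2

    gamma2 = np.full(n_eval, np.inf)
    for off, s2 in zip(offs, space2):
        worst = gamma2.max()
        if s2 >= worst:  # offsets sorted by distance: nothing can improve
            break
        pos = ref_fine + off
        valid = np.all((pos >= 0) & (pos < fine_shape), axis=1)
        if not valid.any():
            continue
        p = pos[valid]
        cand = s2 + (fine[p[:, 0], p[:, 1], p[:, 2]] - dref[valid]) ** 2 / tol_gy**2
        gamma2[valid] = np.minimum(gamma2[valid], cand)

    gamma = np.sqrt(gamma2)
    gamma_map = np.full(grid.shape, np.nan)
    gamma_map[ref_mask] = gamma
    pass_rate = 100.0 * float((gamma <= 1.0).sum()) / n_eval
    return GammaResult(gamma_map=gamma_map, pass_rate_percent=pass_rate,
                       n_evaluated=n_eval, criteria=criteria)
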