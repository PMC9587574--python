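"""Voxel lattice geometry and named binary structure sets.

Everything downstream (component analysis, margin growth, dose surrogates)
operates on boolean occupancy arrays tied to a :class:`GridSpec` that carries
the physical voxel spacing in millimetres.  World coordinates follow the
convention ``world = origin + index * spacing`` with 0-based indices, so voxel
``(0, 0, 0)`` has its *center* at ``origin``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["GridSpec", "StructureSet", "save_mask", "load_mask"]


@dataclass(frozen=True)
class GridSpec:
    """A 3D voxel lattice with anisotropic physical spacing.

    Parameters
    ----------
    shape
        Voxels per axis; every entry >= 1.
    spacing
        Millimetres per voxel along each axis; every entry > 0.
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("GridSpec is strictly three-dimensional")
        if any(int(s) < 1 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_diagonal_mm(self) -> float:
        return float(np.linalg.norm(self.spacing))

    def center_mm(self) -> np.ndarray:
        """World coordinates of the lattice midpoint."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing)

    def empty_mask(self) -> np.ndarray:
        return np.zeros(self.shape, dtype=bool)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, world) -> np.ndarray:
        return (np.asarray(world, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains_point(self, world) -> bool:
        idx = self.world_to_index(world)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.asarray(self.shape) - 0.5))

    def voxel_centers_mm(self, mask: np.ndarray) -> np.ndarray:
        """(n, 3) world coordinates of the occupied voxel centers."""
        return self.index_to_world(np.argwhere(mask))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def validate_mask(self, mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask)
        if mask.shape != self.shape:
            raise ValueError(f"mask shape {mask.shape} does not match grid {self.shape}")
        return mask.astype(bool, copy=False)


@dataclass
class StructureSet:
    """Named binary masks (GTV, edema, brain, ...) sharing one grid."""

    grid: GridSpec
    structures: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mask in self.structures.items():
            self.structures[name] = self.grid.validate_mask(mask)

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    def __getitem__(self, name: str) -> np.ndarray:
        return self.structures[name]

    def __setitem__(self, name: str, mask: np.ndarray) -> None:
        self.structures[name] = self.grid.validate_mask(mask)

    def names(self) -> list[str]:
        return list(self.structures)

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.structures]
        if missing:
            raise KeyError(f"structure set is missing: {', '.join(missing)}")

    def copy(self) -> "StructureSet":
        return StructureSet(self.grid, {k: v.copy() for k, v in self.structures.items()})

    # ---- persistence: directory of NIfTI masks + JSON manifest ----

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, mask in self.structures.items():
            save_mask(mask, self.grid, directory / f"{name}.nii.gz")
        manifest = {
            "grid": {"shape": self.grid.shape, "spacing": self.grid.spacing, "origin": self.grid.origin},
            "structures": sorted(self.structures),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "StructureSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        g = manifest["grid"]
        grid = GridSpec(tuple(g["shape"]), tuple(g["spacing"]), tuple(g["origin"]))
        structures = {}
        for name in manifest["structures"]:
            mask, _ = load_mask(directory / f"{name}.nii.gz")
            structures[name] = mask
        return cls(grid, structures)


def save_mask(mask: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), grid.affine())
    nib.save(img, str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    aff = img.affine
    grid = GridSpec(tuple(data.shape), tuple(float(aff[i, i]) for i in range(3)),
                    tuple(float(aff[i, 3]) for i in range(3)))
    return data.astype(bool), grid
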