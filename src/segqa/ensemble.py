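"""Voxelwise majority-vote fusion of multiple models' binary predictions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import StructureSet

__all__ = ["VotePanel", "majority_vote", "vote_per_structure"]


@dataclass
class VotePanel:
    """Per-model masks on one grid plus the minimum vote count for inclusion.

    The default threshold is the strict majority floor(n/2) + 1 (3 of 5), so
    an exact tie on an even panel is excluded — the conservative choice for
    segmentation.
    """

    masks: list
    threshold: int | None = None

    def __post_init__(self) -> None:
        if len(self.masks) < 1:
            raise ValueError("vote panel needs at least one mask")
        shape = np.asarray(self.masks[0]).shape
        if any(np.asarray(m).shape != shape for m in self.masks):
            raise ValueError("all panel masks must share one grid shape")
        if self.threshold is None:
            self.threshold = len(self.masks) // 2 + 1
        if not 1 <= self.threshold <= len(self.masks):
            raise ValueError(f"threshold must be in [1, {len(self.masks)}], got {self.threshold}")


def majority_vote(panel: VotePanel) -> np.ndarray:
    """Keep a voxel iff at least ``threshold`` models predicted it."""
    votes = np.sum([np.asarray(m, dtype=bool) for m in panel.masks], axis=0)
    return votes >= panel.threshold


def vote_per_structure(sets: list[StructureSet], names, threshold: int | None = None) -> StructureSet:
    """Fuse a list of structure sets, voting independently per structure name."""
    if not sets:
        raise ValueError("no structure sets to fuse")
    grid = sets[0].grid
    for s in sets:
        if s.grid != grid:
            raise ValueError("all structure sets must share one grid")
        s.require(*names)
    fused = StructureSet(grid)
    for name in names:
        fused[name] = majority_vote(VotePanel([s[name] for s in sets], threshold))
    return fused
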