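"""Seeded region growing for airway lumen extraction.

The lumen of an air-filled airway is a dark, connected region in a CT-like
volume; growing a connected component of an intensity band from a seed in
the trachea recovers it.  No leak control is attempted: on real CT thin
airway walls can let the region escape into parenchyma, and the quality of
everything downstream depends on the mask — that robustness problem is out
of scope here and documented as a limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import BinaryMask, ImageVolume

__all__ = ["RegionGrowingParams", "region_grow", "largest_component_cleanup"]


@dataclass
class RegionGrowingParams:
    seed: tuple[int, int, int]      # voxel index (ix, iy, iz)
    lower: float
    upper: float
    connectivity: int = 26          # 6 or 26

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("intensity bounds must be finite")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def region_grow(volume: ImageVolume, params: RegionGrowingParams) -> BinaryMask:
    """Connected component of {lower <= I <= upper} containing the seed.

    Grid metadata is copied from the input so the mask stays registered to
    the volume.  A seed whose intensity falls outside the band raises, since
    growing from it would silently return an unrelated region.
    """
    seed = tuple(int(i) for i in params.seed)
    shape = volume.shape
    if len(seed) != 3 or any(not (0 <= seed[k] < shape[k]) for k in range(3)):
        raise ValueError(f"seed {seed} outside grid of shape {shape}")
    seed_val = float(volume.voxels[seed])
    if not (params.lower <= seed_val <= params.upper):
        raise ValueError(
            f"seed intensity {seed_val} outside bounds "
            f"[{params.lower}, {params.upper}]: bad seed placement"
        )
    band = (volume.voxels >= params.lower) & (volume.voxels <= params.upper)
    labels, _ = ndimage.label(band, structure=_structure(params.connectivity))
    region = labels == labels[seed]
    return BinaryMask(voxels=region, spacing=volume.spacing, origin=volume.origin)


def largest_component_cleanup(mask: BinaryMask) -> BinaryMask:
    """Keep only the largest 26-connected component.

    Ties are broken by keeping the component that contains the
    lexicographically smallest voxel index.
    """
    if mask.foreground_count() == 0:
        raise ValueError("empty mask: nothing to clean up")
    labels, n = ndimage.label(mask.voxels, structure=_structure(26))
    if n == 1:
        return mask
    counts = np.bincount(labels.ravel())[1:]  # skip background
    best = counts.max()
    tied = np.flatnonzero(counts == best) + 1
    if len(tied) == 1:
        keep = tied[0]
    else:
        # lexicographically first foreground voxel among tied components wins;
        # np.argwhere yields indices in lexicographic (C) order
        first_idx = {
            lab: tuple(np.argwhere(labels == lab)[0]) for lab in tied
        }
        keep = min(tied, key=lambda lab: first_idx[lab])
    return BinaryMask(voxels=(labels == keep), spacing=mask.spacing, origin=mask.origin)
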