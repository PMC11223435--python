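"""Pipeline configuration: every tunable in one serializable place.

Each run writes the fully resolved config next to its outputs so results
are traceable to the exact parameter set that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    """Tunables for the geometry pipeline and the cohort statistics.

    Geometric quantities are in mm and degrees.  ``resample_step_h`` sets the
    arc-length sampling density of every centerline; smoothing scales
    (``smooth_sigma_mm``, ``frenet_sigma_mm``) are expressed in mm so their
    effect is independent of voxel size.
    """

    # segmentation
    connectivity: int = 26                 # region growing neighborhood (6 or 26)

    # surface
    smoothing_iterations: int = 30         # Taubin passes on the extracted mesh
    target_edge_ratio: float = 4.0         # max/min triangle edge length bound

    # centerline
    resample_step_h: float = 0.5           # mm, uniform arc-length step
    smooth_sigma_mm: float = 1.0           # mm, Gaussian smoothing of voxel paths
    medial_exponent: float = 2.0           # clearance weighting power in path cost
    min_branch_length: float = 3.0         # mm, skeleton endpoint pruning
    frenet_sigma_mm: float = 1.0           # mm, smoothing before derivatives (= 2h)

    # tree
    merge_tol: float = 0.5                 # mm, polyline coincidence tolerance (= h)
    tangent_window_w: float = 6.0          # mm, tangent averaging for angles
    junction_buffer: float = 1.0           # mm, margin added to the local tube
                                           # radius when skipping the junction
                                           # pocket before averaging tangents

    # cross-sections
    contour_step: float = 0.2              # mm, cut-contour resampling step

    # lesion mapping
    max_lesion_distance: float = 50.0      # mm, beyond this: "no leading bronchus"

    # cohort statistics
    n_boot: int = 1000
    holdout: float = 0.3
    caliper: float = 0.25                  # x SD of the propensity logit
    rf_trees: int = 512
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
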