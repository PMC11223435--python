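"""End-to-end orchestration: mask (or volume) -> tree -> feature table.

Each run is deterministic given its config and writes the fully resolved
config (with its hash) as a JSON sidecar next to the outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import features as feat
from . import geometry as geom
from .config import PipelineConfig
from .imaging import BinaryMask, ImageVolume, write_feature_table
from .segmentation import RegionGrowingParams, largest_component_cleanup, region_grow

logger = logging.getLogger("airwaygeom")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    tree: geom.AirwayTree
    feature_row: dict
    mask: BinaryMask
    mesh: object
    centerlines: list[geom.CenterlinePolyline]
    degraded: bool          # True when no lesion was given (no Branch renumbering)


def run_pipeline(
    source: ImageVolume | BinaryMask,
    lesion: np.ndarray | None,
    config: PipelineConfig | None = None,
    region_growing: RegionGrowingParams | None = None,
    out_csv: str | Path | None = None,
    out_tree: str | Path | None = None,
) -> PipelineResult:
    """Run segment (if needed) -> surface -> centerlines -> tree -> features.

    ``source`` may already be a mask; otherwise ``region_growing`` params are
    required to extract one.  Without a lesion the pipeline degrades to
    per-section features with no Branch numbering and no global features.
    """
    cfg = config or PipelineConfig()
    if isinstance(source, BinaryMask):
        mask = source
    else:
        if region_growing is None:
            raise ValueError("a scalar volume input needs region-growing parameters")
        logger.info("stage=segment")
        mask = region_grow(source, region_growing)
        mask = largest_component_cleanup(mask)
    logger.info("stage=surface foreground=%d", mask.foreground_count())
    mesh = geom.extract_surface(mask, cfg)
    logger.info("stage=skeleton")
    root, endpoints = geom.detect_root_and_endpoints(mask, cfg)
    logger.info("stage=centerlines endpoints=%d", len(endpoints))
    polylines = geom.extract_centerlines(mesh, mask, root, endpoints, cfg)
    for p in polylines:
        geom.estimate_frenet(p, cfg)
    logger.info("stage=tree")
    tree = geom.build_tree(polylines, cfg)
    logger.info("stage=features sections=%d", len(tree.sections))
    row = feat.case_feature_row(tree, mask, lesion, cfg, mesh=mesh)
    degraded = lesion is None

    if out_csv is not None:
        provenance = {
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "spacing": list(mask.spacing),
            "origin": list(mask.origin),
            "lesion": None if lesion is None else list(map(float, np.asarray(lesion))),
            "degraded": degraded,
            "n_sections": len(tree.sections),
        }
        write_feature_table([row], out_csv, provenance=provenance)
    if out_tree is not None:
        Path(out_tree).parent.mkdir(parents=True, exist_ok=True)
        Path(out_tree).write_text(tree.to_json())
    return PipelineResult(
        tree=tree, feature_row=row, mask=mask, mesh=mesh,
        centerlines=polylines, degraded=degraded,
    )
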