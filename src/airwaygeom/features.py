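"""Per-branch-section and path-level geometric features.

Every retained centerline point of a branch section gets a cross-sectional
cut of the lumen perpendicular to the local tangent; nine per-point families
(sectional area, inscribed-sphere radius, min/max Feret diameter and their
ratio, curvature, torsion, perimeter, circularity) are aggregated per
section with minimum / maximum / average / sample standard deviation.
Together with the section length and the entry bifurcation angle this gives
38 local features per branch section.  The root-to-lesion path contributes
6 global features: the total path length and five statistics (sum, min,
max, average, SD) of the bifurcation angles along it.

Branch numbering follows the lesion: the section closest to the lesion is
Branch 0 and numbers increase proximally toward the trachea.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .config import PipelineConfig
from .geometry import AirwayTree, BranchSection, GeometryError
from .imaging import BinaryMask

__all__ = [
    "CrossSection",
    "cut_cross_section",
    "section_features",
    "find_branch0",
    "path_features",
    "case_feature_row",
    "FAMILIES",
    "STATISTICS",
    "GLOBAL_FEATURES",
    "LOCAL_FEATURES_PER_SECTION",
]

FAMILIES = (
    "SectionalArea",
    "MaxInscribedSphereR",
    "MinDiameter",
    "MaxDiameter",
    "MinMaxDiameterRatio",
    "Curvature",
    "Torsion",
    "Perimeter",
    "LuminalCircularity",
)
STATISTICS = ("Minimum", "Maximum", "Average", "StdDev")
GLOBAL_FEATURES = (
    "TotalLength",
    "BifurcationAngleSum",
    "BifurcationAngleMinimum",
    "BifurcationAngleMaximum",
    "BifurcationAngleAverage",
    "BifurcationAngleStdDev",
)
LOCAL_FEATURES_PER_SECTION = 2 + len(FAMILIES) * len(STATISTICS)  # 38


@dataclass
class CrossSection:
    """Planar lumen cut perpendicular to the centerline tangent."""

    origin: np.ndarray          # mm
    normal: np.ndarray          # unit tangent
    contour: np.ndarray         # (m, 2) in-plane mm polygon, closed implicitly
    sectional_area: float       # mm^2
    perimeter: float            # mm
    min_diameter: float         # mm (min Feret)
    max_diameter: float         # mm (max Feret)

    @property
    def min_max_diameter_ratio(self) -> float:
        return self.min_diameter / self.max_diameter

    @property
    def luminal_circularity(self) -> float:
        return 4.0 * np.pi * self.sectional_area / self.perimeter**2


def _plane_basis(normal: np.ndarray):
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    ref = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return n, u, v


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _polygon_perimeter(pts: np.ndarray) -> float:
    closed = np.vstack([pts, pts[:1]])
    return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


def _feret_diameters(pts: np.ndarray) -> tuple[float, float]:
    """Min/max Feret diameters of a planar point set via its convex hull.

    Max Feret = hull diameter; min Feret = minimal width over hull edge
    directions (rotating calipers).
    """
    hull = ConvexHull(pts)
    hp = pts[hull.vertices]
    # max: diameter of the hull point set
    diffs = hp[:, None, :] - hp[None, :, :]
    dmax = float(np.sqrt((diffs**2).sum(-1)).max())
    # min: smallest width across hull edges
    edges = np.roll(hp, -1, axis=0) - hp
    lengths = np.linalg.norm(edges, axis=1)
    keep = lengths > 1e-12
    normals = np.stack([-edges[keep][:, 1], edges[keep][:, 0]], axis=1)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    proj = hp @ normals.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min()), dmax


def _point_in_polygon(pt: np.ndarray, poly: np.ndarray) -> bool:
    """Ray-casting point-in-polygon test for a simple 2D polygon."""
    x, y = pt
    xs, ys = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(xs, -1), np.roll(ys, -1)
    crosses = ((ys > y) != (y2 > y)) & (
        x < xs + (y - ys) * (x2 - xs) / np.where(y2 != ys, y2 - ys, np.inf)
    )
    return bool(crosses.sum() % 2)


def _resample_contour(poly: np.ndarray, step: float) -> np.ndarray:
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(np.ceil(s[-1] / step)), 8)
    s_new = np.linspace(0.0, s[-1], n, endpoint=False)
    return np.column_stack([np.interp(s_new, s, closed[:, k]) for k in range(2)])


def cut_cross_section(
    mask: BinaryMask,
    point: np.ndarray,
    tangent: np.ndarray,
    config: PipelineConfig | None = None,
    mesh=None,
) -> CrossSection:
    """Contour the lumen in the plane through ``point`` normal to ``tangent``.

    The cut is the intersection of the smoothed surface model with the
    plane: of the closed intersection polygons, the one enclosing ``point``
    is the luminal contour (a plane can also slice sibling branches; those
    polygons do not enclose the point and are discarded).  Pass the mesh
    from :func:`airwaygeom.geometry.extract_surface` when cutting many
    sections of the same mask; otherwise it is extracted on the fly.
    """
    cfg = config or PipelineConfig()
    point = np.asarray(point, dtype=float)
    idx = np.round(mask.world_to_index(point)).astype(int)
    if (idx < 0).any() or (idx >= np.array(mask.shape)).any() or mask.voxels[tuple(idx)] == 0:
        raise GeometryError(f"cross-section point {point} is not inside the lumen")
    if mesh is None:
        from .geometry import extract_surface

        mesh = extract_surface(mask, cfg)
    n, u, v = _plane_basis(tangent)

    section = mesh.section(plane_origin=point, plane_normal=n)
    if section is None or len(section.discrete) == 0:
        raise GeometryError(f"the cut plane at {point} misses the surface")
    polygons = []
    for poly3d in section.discrete:
        pts = np.asarray(poly3d)
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            continue
        rel = pts - point
        polygons.append(np.column_stack([rel @ u, rel @ v]))
    containing = [p for p in polygons if _point_in_polygon(np.zeros(2), p)]
    if containing:
        # smallest enclosing polygon = the lumen wall (outer ones are e.g.
        # a parent lumen sliced obliquely around it)
        contour = min(containing, key=_polygon_area)
    else:
        # centerline jitter can put the point marginally outside the wall;
        # fall back to the nearest polygon
        def dist(p):
            return float(np.linalg.norm(p, axis=1).min())
        contour = min(polygons, key=dist)

    area = _polygon_area(contour)
    perim = _polygon_perimeter(contour)
    dmin, dmax = _feret_diameters(contour)
    return CrossSection(
        origin=point, normal=n,
        contour=_resample_contour(contour, cfg.contour_step),
        sectional_area=area, perimeter=perim,
        min_diameter=dmin, max_diameter=dmax,
    )


def _stats(values: np.ndarray) -> dict[str, float]:
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return {
        "Minimum": float(values.min()),
        "Maximum": float(values.max()),
        "Average": float(values.mean()),
        "StdDev": sd,
    }


def section_features(
    section: BranchSection,
    mask: BinaryMask,
    config: PipelineConfig | None = None,
    mesh=None,
) -> dict:
    """The 38 local features of one branch section.

    Cross-sections are cut at every resampled centerline point except those
    within one local radius of either section end, where the cut would merge
    sibling lumens at a bifurcation.  If fewer than 3 points survive the
    exclusion, all points are used and the row is flagged.
    """
    cfg = config or PipelineConfig()
    s = section.arclength
    total = float(s[-1])
    # one tube radius (robust: the median) excluded at each end, where cuts
    # would straddle a bifurcation or the lumen cap
    r_med = float(np.median(section.radius))
    keep = (s >= r_med) & ((total - s) >= r_med)
    flagged = False
    if keep.sum() < 3:
        keep = np.ones(len(s), dtype=bool)
        flagged = True

    pts = section.points[keep]
    radii = section.radius[keep]
    kappa = None if section.curvature is None else section.curvature[keep]
    tau = None if section.torsion is None else section.torsion[keep]

    # local tangents from the section polyline itself
    tangents = np.gradient(section.points, axis=0)
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1, keepdims=True), 1e-12)
    tangents = tangents[keep]

    if mesh is None:
        from .geometry import extract_surface

        mesh = extract_surface(mask, cfg)
    areas, perims, dmins, dmaxs = [], [], [], []
    for p, t in zip(pts, tangents):
        cs = cut_cross_section(mask, p, t, cfg, mesh=mesh)
        areas.append(cs.sectional_area)
        perims.append(cs.perimeter)
        dmins.append(cs.min_diameter)
        dmaxs.append(cs.max_diameter)
    areas = np.array(areas); perims = np.array(perims)
    dmins = np.array(dmins); dmaxs = np.array(dmaxs)

    family_values = {
        "SectionalArea": areas,
        "MaxInscribedSphereR": radii,
        "MinDiameter": dmins,
        "MaxDiameter": dmaxs,
        "MinMaxDiameterRatio": dmins / dmaxs,
        "Curvature": kappa if kappa is not None else np.zeros(len(pts)),
        "Torsion": tau if tau is not None else np.zeros(len(pts)),
        "Perimeter": perims,
        "LuminalCircularity": 4.0 * np.pi * areas / perims**2,
    }
    row: dict = {
        "BifurcationAngleIn": section.bifurcation_angle_in,
        "SectionalLength": float(section.section_length),
    }
    for fam in FAMILIES:
        for stat, val in _stats(family_values[fam]).items():
            row[f"{fam}{stat}"] = val
    row["_endcap_flagged"] = flagged  # provenance only; stripped from tables
    return row


def find_branch0(
    tree: AirwayTree,
    lesion: np.ndarray,
    config: PipelineConfig | None = None,
) -> tuple[BranchSection, list[int]]:
    """Locate Branch 0 (closest section to the lesion) and its root path.

    Returns the section and the section-id path ordered root -> Branch 0.
    Ties in distance go to the lower section id.  A lesion farther than
    ``max_lesion_distance`` from every centerline point has no leading
    bronchus and raises.
    """
    cfg = config or PipelineConfig()
    lesion = np.asarray(lesion, dtype=float)
    best = (np.inf, None)
    for sid in sorted(tree.sections):
        d = float(np.linalg.norm(tree.sections[sid].points - lesion, axis=1).min())
        if d < best[0] - 1e-12:
            best = (d, sid)
    dist, sid = best
    if sid is None or dist > cfg.max_lesion_distance:
        raise GeometryError(
            f"no leading bronchus: lesion is {dist:.1f} mm from the nearest "
            f"centerline (limit {cfg.max_lesion_distance} mm)"
        )
    return tree.sections[sid], tree.path_to_root(sid)


def path_features(path_rows: list[dict], path_sections: list[BranchSection]) -> dict:
    """The 6 global features of a root -> Branch 0 path.

    ``path_sections`` is ordered root -> Branch 0.  The root section has no
    entry angle; missing angles are excluded (not imputed as zero).  A path
    with only the root section gets null angle statistics but a total length.
    """
    total = float(sum(s.section_length for s in path_sections))
    angles = np.array(
        [s.bifurcation_angle_in for s in path_sections if s.bifurcation_angle_in is not None],
        dtype=float,
    )
    if angles.size == 0:
        return {
            "TotalLength": total,
            "BifurcationAngleSum": None,
            "BifurcationAngleMinimum": None,
            "BifurcationAngleMaximum": None,
            "BifurcationAngleAverage": None,
            "BifurcationAngleStdDev": None,
        }
    return {
        "TotalLength": total,
        "BifurcationAngleSum": float(angles.sum()),
        "BifurcationAngleMinimum": float(angles.min()),
        "BifurcationAngleMaximum": float(angles.max()),
        "BifurcationAngleAverage": float(angles.mean()),
        "BifurcationAngleStdDev": float(np.std(angles, ddof=1)) if angles.size > 1 else 0.0,
    }


def case_feature_row(
    tree: AirwayTree,
    mask: BinaryMask,
    lesion: np.ndarray | None,
    config: PipelineConfig | None = None,
    mesh=None,
) -> dict:
    """One flat feature row for a case: path branches + global features.

    With a lesion, sections on the root->lesion path are renumbered
    Branch 0 (distal, closest to the lesion) .. Branch n (root) and each
    contributes its 38 local features with a ``_Branch<k>`` suffix, plus the
    6 global path features.  Without a lesion (degraded mode) every section
    is emitted under its tree section id (``_Section<i>``) and no globals
    are computed.
    """
    cfg = config or PipelineConfig()
    if lesion is None:
        row: dict = {}
        for sid in sorted(tree.sections):
            sec_row = section_features(tree.sections[sid], mask, cfg, mesh=mesh)
            sec_row.pop("_endcap_flagged", None)
            for k, v in sec_row.items():
                row[f"{k}_Section{sid}"] = v
        return row

    _, path = find_branch0(tree, lesion, cfg)
    path_sections = [tree.sections[sid] for sid in path]
    row = {}
    rows = []
    # Branch 0 is the most distal section of the path
    for k, sec in enumerate(reversed(path_sections)):
        sec_row = section_features(sec, mask, cfg, mesh=mesh)
        sec_row.pop("_endcap_flagged", None)
        rows.append(sec_row)
        for name, val in sec_row.items():
            row[f"{name}_Branch{k}"] = val
    row.update(path_features(rows, path_sections))
    return row
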