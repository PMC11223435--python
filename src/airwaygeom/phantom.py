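"""Parametric tubular-tree phantoms with analytic ground truth.

The phantom module is the project's oracle: every tube is a closed-form space
curve (straight line, torus arc, or circular helix) swept by a disc of fixed
radius, so centerline position, curvature, torsion, lumen radius, section
length and bifurcation angle are known exactly, by construction.  The
rasterizer marks a voxel as lumen iff its center lies within one tube radius
of a segment's centerline curve (no partial volume), which makes the
brute-force voxel test and the rasterizer literally the same rule.

Closed forms used as ground truth (magnitudes):
    straight:   kappa = 0,            tau = 0
    torus arc:  kappa = 1/R,          tau = 0
    helix:      kappa = R/(R^2+c^2),  tau = c/(R^2+c^2)
with bend radius R (mm) and helix pitch c (mm per radian of sweep).

A small builder API (`straight`, `torus_arc`, `helix`, `attach`) constructs
trees where each child starts on the parent's end point with a declared
axis-to-axis bifurcation angle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .imaging import BinaryMask, ImageVolume

__all__ = [
    "TubeSegmentSpec",
    "PhantomTreeSpec",
    "PhantomGroundTruth",
    "rasterize_phantom",
    "sample_synthetic_cohort",
    "TABLE_EFFECTS",
]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


def _any_perpendicular(d: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(d, ref))


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    axis = _unit(axis)
    return (
        v * np.cos(angle_rad)
        + np.cross(axis, v) * np.sin(angle_rad)
        + axis * np.dot(axis, v) * (1.0 - np.cos(angle_rad))
    )


@dataclass
class TubeSegmentSpec:
    """One tube: a closed-form centerline curve swept by a disc of radius r.

    ``direction`` is the unit tangent at the start point.  For ``torus_arc``
    the curve bends toward ``bend_normal`` (a unit vector perpendicular to
    ``direction`` pointing from the start toward the bend center).  For
    ``helix`` the same vector points from the start toward the helix axis and
    ``pitch`` is the rise in mm per radian of sweep.
    """

    name: str
    kind: str                       # straight | torus_arc | helix
    radius: float                   # tube radius r, mm
    start: np.ndarray               # mm
    direction: np.ndarray           # unit tangent at start
    length: float | None = None     # mm (straight)
    arc_deg: float | None = None    # swept angle (torus_arc, helix)
    bend_radius: float | None = None  # R, mm (torus_arc, helix)
    pitch: float | None = None      # c, mm/radian (helix)
    bend_normal: np.ndarray | None = None
    parent: str | None = None
    declared_angle_deg: float | None = None  # axis angle vs parent at junction

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "torus_arc", "helix"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("tube radius must be positive")
        self.start = np.asarray(self.start, dtype=float)
        self.direction = _unit(self.direction)
        if self.kind == "straight":
            if self.length is None or self.length <= 0:
                raise ValueError("straight segment needs length > 0")
        else:
            if self.arc_deg is None or not (0 < self.arc_deg <= 360):
                raise ValueError("arc segment needs 0 < arc_deg <= 360")
            if self.bend_radius is None or self.bend_radius <= 0:
                raise ValueError("arc segment needs bend_radius > 0")
            if self.kind == "torus_arc" and self.bend_radius <= self.radius:
                raise ValueError(
                    "bend_radius must exceed tube radius (self-intersecting torus)"
                )
            if self.bend_normal is None:
                self.bend_normal = _any_perpendicular(self.direction)
            else:
                self.bend_normal = _unit(self.bend_normal)
                if abs(np.dot(self.bend_normal, self.direction)) > 1e-8:
                    # re-orthogonalize against the tangent
                    bn = self.bend_normal - np.dot(self.bend_normal, self.direction) * self.direction
                    self.bend_normal = _unit(bn)
            if self.kind == "helix" and (self.pitch is None):
                raise ValueError("helix needs pitch (mm/radian)")

    # ---- analytic curve ---------------------------------------------------

    def arc_length(self) -> float:
        if self.kind == "straight":
            return float(self.length)
        theta = np.deg2rad(self.arc_deg)
        R = self.bend_radius
        if self.kind == "torus_arc":
            return float(R * theta)
        c = self.pitch
        return float(theta * np.hypot(R, c))

    def curve(self, s: np.ndarray) -> np.ndarray:
        """Centerline points at arc lengths ``s`` (mm), shape (n, 3)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        d = self.direction
        if self.kind == "straight":
            return self.start[None, :] + s[:, None] * d[None, :]
        R = self.bend_radius
        n = self.bend_normal
        if self.kind == "torus_arc":
            center = self.start + R * n
            u = -n                       # center -> start
            v = d
            phi = s / R
            return (
                center[None, :]
                + R * (np.cos(phi)[:, None] * u[None, :] + np.sin(phi)[:, None] * v[None, :])
            )
        # helix: recover the axis from the start tangent.  With radial u
        # (axis point -> start) and b = u x d, the start tangent satisfies
        # d*speed = R*(a x u) + c*a, whose solution in span{d, b} is
        # a = (c*d + R*b)/speed.
        c = self.pitch
        speed = np.hypot(R, c)
        u = -n
        b_dir = _unit(np.cross(u, d))
        axis = _unit((c * d + R * b_dir) / speed)
        v = np.cross(axis, u)
        center0 = self.start + R * n
        phi = s / speed
        return (
            center0[None, :]
            + R * (np.cos(phi)[:, None] * u[None, :] + np.sin(phi)[:, None] * v[None, :])
            + (c * phi)[:, None] * axis[None, :]
        )

    def tangent(self, s: np.ndarray) -> np.ndarray:
        """Unit tangents at arc lengths ``s`` (finite-difference free)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        eps = 1e-4
        p1 = self.curve(np.clip(s + eps, 0, self.arc_length()))
        p0 = self.curve(np.clip(s - eps, 0, self.arc_length()))
        t = p1 - p0
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def end_point(self) -> np.ndarray:
        return self.curve(np.array([self.arc_length()]))[0]

    def end_tangent(self) -> np.ndarray:
        return self.tangent(np.array([self.arc_length()]))[0]

    def kappa_true(self) -> float:
        if self.kind == "straight":
            return 0.0
        R = self.bend_radius
        if self.kind == "torus_arc":
            return 1.0 / R
        c = self.pitch
        return R / (R * R + c * c)

    def tau_true(self) -> float:
        if self.kind != "helix":
            return 0.0
        R, c = self.bend_radius, self.pitch
        return c / (R * R + c * c)

    def analytic_volume(self) -> float:
        """Tube volume pi r^2 L (exact for straight; Pappus for arcs)."""
        return float(np.pi * self.radius**2 * self.arc_length())


@dataclass
class PhantomTreeSpec:
    """A rooted tree of tube segments plus rasterization parameters."""

    segments: list[TubeSegmentSpec]
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    foreground: float = -1000.0     # air-like lumen intensity
    background: float = 0.0         # soft-tissue-like surroundings
    noise_sd: float = 0.0           # optional additive Gaussian noise
    noise_seed: int = 0
    pad_mm: float = 2.0
    lesion_point: np.ndarray | None = None
    lesion_segment: str | None = None   # name a terminal segment instead

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names")
        by_name = {s.name: s for s in self.segments}
        n_roots = 0
        for s in self.segments:
            if s.parent is None:
                n_roots += 1
            else:
                if s.parent not in by_name:
                    raise ValueError(f"segment {s.name!r} has unknown parent {s.parent!r}")
                p = by_name[s.parent]
                if not np.allclose(s.start, p.end_point(), atol=1e-6):
                    raise ValueError(
                        f"segment {s.name!r} must start on its parent's centerline end"
                    )
        if n_roots != 1:
            raise ValueError(f"expected exactly one root segment, found {n_roots}")
        if self.lesion_segment is not None and self.lesion_segment not in by_name:
            raise ValueError(f"unknown lesion segment {self.lesion_segment!r}")
        if self.lesion_point is not None:
            self.lesion_point = np.asarray(self.lesion_point, dtype=float)

    @property
    def root(self) -> TubeSegmentSpec:
        return next(s for s in self.segments if s.parent is None)

    def resolve_lesion(self) -> np.ndarray | None:
        """Lesion coordinate in mm; the end of ``lesion_segment`` if named."""
        if self.lesion_point is not None:
            return self.lesion_point
        if self.lesion_segment is not None:
            seg = next(s for s in self.segments if s.name == self.lesion_segment)
            return seg.end_point()
        return None

    # JSON round trip for CLI configs
    def to_json(self) -> str:
        def seg_dict(s: TubeSegmentSpec) -> dict:
            return {
                "name": s.name, "kind": s.kind, "radius": s.radius,
                "start": list(s.start), "direction": list(s.direction),
                "length": s.length, "arc_deg": s.arc_deg,
                "bend_radius": s.bend_radius, "pitch": s.pitch,
                "bend_normal": None if s.bend_normal is None else list(s.bend_normal),
                "parent": s.parent, "declared_angle_deg": s.declared_angle_deg,
            }
        return json.dumps(
            {
                "segments": [seg_dict(s) for s in self.segments],
                "spacing": list(self.spacing),
                "foreground": self.foreground,
                "background": self.background,
                "noise_sd": self.noise_sd,
                "noise_seed": self.noise_seed,
                "pad_mm": self.pad_mm,
                "lesion_point": None if self.lesion_point is None else list(self.lesion_point),
                "lesion_segment": self.lesion_segment,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PhantomTreeSpec":
        d = json.loads(text)
        segs = [TubeSegmentSpec(**{**sd, "start": np.array(sd["start"]),
                                   "direction": np.array(sd["direction"]),
                                   "bend_normal": None if sd["bend_normal"] is None
                                   else np.array(sd["bend_normal"])})
                for sd in d["segments"]]
        return cls(
            segments=segs, spacing=tuple(d["spacing"]), foreground=d["foreground"],
            background=d["background"], noise_sd=d["noise_sd"],
            noise_seed=d["noise_seed"], pad_mm=d["pad_mm"],
            lesion_point=None if d["lesion_point"] is None else np.array(d["lesion_point"]),
            lesion_segment=d["lesion_segment"],
        )


@dataclass
class PhantomGroundTruth:
    """Analytic truth per segment and junction, for use as a test oracle."""

    segments: dict[str, TubeSegmentSpec]
    kappa_true: dict[str, float]
    tau_true: dict[str, float]
    radius_true: dict[str, float]
    length_true: dict[str, float]
    angle_true: dict[str, float]            # child name -> degrees
    analytic_volume: float                  # sum of per-tube volumes (overlap not removed)
    lesion: np.ndarray | None = None

    def sample_centerline(self, name: str, step: float = 0.5) -> np.ndarray:
        """Points on the true centerline of a segment at uniform arc step."""
        seg = self.segments[name]
        L = seg.arc_length()
        n = max(int(np.floor(L / step)) + 1, 2)
        s = np.linspace(0.0, L, n)
        return seg.curve(s)

    def path_centerline(self, names: list[str], step: float = 0.5) -> np.ndarray:
        pts = [self.sample_centerline(n, step) for n in names]
        out = [pts[0]]
        for p in pts[1:]:
            out.append(p[1:])  # drop duplicated junction point
        return np.vstack(out)

    def distance_to_axis(self, name: str, points: np.ndarray) -> np.ndarray:
        """Distance from query points to the segment's analytic centerline."""
        dense = self.sample_centerline(name, step=0.02)
        tree = cKDTree(dense)
        d, _ = tree.query(np.atleast_2d(points))
        return d


# ---- builders --------------------------------------------------------------


def straight(name: str, radius: float, length: float,
             start=(0.0, 0.0, 0.0), direction=(0.0, 0.0, -1.0),
             parent: str | None = None, declared_angle_deg: float | None = None
             ) -> TubeSegmentSpec:
    return TubeSegmentSpec(name=name, kind="straight", radius=radius,
                           start=start, direction=direction, length=length,
                           parent=parent, declared_angle_deg=declared_angle_deg)


def torus_arc(name: str, radius: float, bend_radius: float, arc_deg: float,
              start=(0.0, 0.0, 0.0), direction=(0.0, 0.0, -1.0),
              bend_normal=None, parent: str | None = None,
              declared_angle_deg: float | None = None) -> TubeSegmentSpec:
    return TubeSegmentSpec(name=name, kind="torus_arc", radius=radius,
                           start=start, direction=direction, arc_deg=arc_deg,
                           bend_radius=bend_radius, bend_normal=bend_normal,
                           parent=parent, declared_angle_deg=declared_angle_deg)


def helix(name: str, radius: float, bend_radius: float, pitch: float,
          arc_deg: float, start=(0.0, 0.0, 0.0), direction=None,
          bend_normal=None, parent: str | None = None,
          declared_angle_deg: float | None = None) -> TubeSegmentSpec:
    if bend_normal is None:
        bend_normal = (1.0, 0.0, 0.0)
    if direction is None:
        # any tangent perpendicular to the radial direction works; pick the
        # canonical one for axis +z-like progression
        direction = _unit(np.cross((0.0, 0.0, 1.0), bend_normal))
    return TubeSegmentSpec(name=name, kind="helix", radius=radius,
                           start=start, direction=direction, arc_deg=arc_deg,
                           bend_radius=bend_radius, pitch=pitch,
                           bend_normal=bend_normal, parent=parent,
                           declared_angle_deg=declared_angle_deg)


def attach(parent: TubeSegmentSpec, name: str, radius: float, length: float,
           angle_deg: float, azimuth_deg: float = 0.0) -> TubeSegmentSpec:
    """Attach a straight child at the parent's end with a declared angle.

    The child axis is the parent's end tangent rotated by ``angle_deg`` about
    an axis perpendicular to it chosen by ``azimuth_deg``, so the declared
    bifurcation angle equals the axis-to-axis angle by construction.
    """
    t = parent.end_tangent()
    e1 = _any_perpendicular(t)
    e2 = np.cross(t, e1)
    rot_axis = np.cos(np.deg2rad(azimuth_deg)) * e1 + np.sin(np.deg2rad(azimuth_deg)) * e2
    child_dir = _rotate_about(t, rot_axis, np.deg2rad(angle_deg))
    return straight(name, radius=radius, length=length,
                    start=parent.end_point(), direction=child_dir,
                    parent=parent.name, declared_angle_deg=float(angle_deg))


def rotate_spec(spec: PhantomTreeSpec, rotation: np.ndarray) -> PhantomTreeSpec:
    """Rigidly rotate a phantom tree about the origin (same tree, new pose)."""
    R = np.asarray(rotation, dtype=float)
    segs = []
    for s in spec.segments:
        segs.append(TubeSegmentSpec(
            name=s.name, kind=s.kind, radius=s.radius,
            start=R @ s.start, direction=R @ s.direction,
            length=s.length, arc_deg=s.arc_deg, bend_radius=s.bend_radius,
            pitch=s.pitch,
            bend_normal=None if s.bend_normal is None else R @ s.bend_normal,
            parent=s.parent, declared_angle_deg=s.declared_angle_deg,
        ))
    return PhantomTreeSpec(
        segments=segs, spacing=spec.spacing, foreground=spec.foreground,
        background=spec.background, noise_sd=spec.noise_sd,
        noise_seed=spec.noise_seed, pad_mm=spec.pad_mm,
        lesion_point=None if spec.lesion_point is None else R @ spec.lesion_point,
        lesion_segment=spec.lesion_segment,
    )


def example_tree(scale: float = 1.0, rotation: np.ndarray | None = None,
                 spacing: float = 0.5) -> PhantomTreeSpec:
    """A three-generation demo airway: trunk, curved child, two grandchildren.

    ``scale`` multiplies every length, radius and the voxel spacing together
    (so the digitized geometry is self-similar); ``rotation`` rigidly rotates
    the finished tree.  The lesion sits at the end of the deepest branch.
    """
    g0 = straight("g0", 3.5 * scale, 28.0 * scale, start=(0, 0, 0),
                  direction=(0, 0, -1))
    ang = np.deg2rad(30.0)
    d1 = np.array([np.sin(ang), 0.0, -np.cos(ang)])
    g1 = TubeSegmentSpec(
        name="g1", kind="torus_arc", radius=2.6 * scale,
        start=g0.end_point(), direction=d1,
        arc_deg=42.0, bend_radius=30.0 * scale,
        bend_normal=np.cross(d1, (0.0, 1.0, 0.0)),
        parent="g0", declared_angle_deg=30.0,
    )
    g1b = attach(g0, "g1b", 2.6 * scale, 18.0 * scale, angle_deg=40.0,
                 azimuth_deg=180.0)
    g2 = attach(g1, "g2", 2.0 * scale, 18.0 * scale, angle_deg=25.0,
                azimuth_deg=90.0)
    g2b = attach(g1, "g2b", 2.0 * scale, 14.0 * scale, angle_deg=45.0,
                 azimuth_deg=270.0)
    spec = PhantomTreeSpec(
        segments=[g0, g1, g1b, g2, g2b],
        spacing=(spacing * scale,) * 3,
        lesion_segment="g2",
    )
    if rotation is not None:
        spec = rotate_spec(spec, rotation)
    return spec


# ---- rasterization ---------------------------------------------------------


def rasterize_phantom(spec: PhantomTreeSpec
                      ) -> tuple[ImageVolume, BinaryMask, PhantomGroundTruth]:
    """Voxelize a phantom tree: lumen = voxel centers within r of a centerline.

    Raises if any tube would be under-resolved (diameter < 4 voxels along the
    coarsest axis), since geometric estimates are meaningless below that.
    """
    spacing = np.asarray(spec.spacing, dtype=float)
    for seg in spec.segments:
        if 2.0 * seg.radius < 4.0 * spacing.max():
            raise ValueError(
                f"segment {seg.name!r}: tube radius {seg.radius} mm under-resolved "
                f"at spacing {tuple(spacing)} (need 2r >= 4*max spacing)"
            )

    # bounding box over dense curve samples plus radius and padding
    dense_step = float(spacing.min()) / 8.0
    curves = {}
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for seg in spec.segments:
        L = seg.arc_length()
        n = max(int(np.ceil(L / dense_step)) + 1, 2)
        pts = seg.curve(np.linspace(0.0, L, n))
        curves[seg.name] = pts
        lo = np.minimum(lo, pts.min(axis=0) - seg.radius)
        hi = np.maximum(hi, pts.max(axis=0) + seg.radius)
    lo -= spec.pad_mm
    hi += spec.pad_mm
    origin = lo
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1

    mask = np.zeros(shape, dtype=np.uint8)
    for seg in spec.segments:
        pts = curves[seg.name]
        r = seg.radius
        # restrict to the voxel sub-box around this tube
        sub_lo = np.maximum(np.floor((pts.min(axis=0) - r - origin) / spacing).astype(int) - 1, 0)
        sub_hi = np.minimum(np.ceil((pts.max(axis=0) + r - origin) / spacing).astype(int) + 1,
                            shape - 1)
        ax = [np.arange(sub_lo[k], sub_hi[k] + 1) for k in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        centers = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) * spacing + origin
        tree = cKDTree(pts)
        d, _ = tree.query(centers, workers=-1)
        inside = d <= r
        # cut the spherical caps: keep only points between the end planes so
        # a lone tube is a true (flat-capped) cylinder/arc of volume pi r^2 L
        t0 = seg.tangent(np.array([0.0]))[0]
        t1 = seg.end_tangent()
        inside &= (centers - seg.start) @ t0 >= 0
        inside &= (centers - seg.end_point()) @ t1 <= 0
        sub = mask[sub_lo[0]:sub_hi[0] + 1, sub_lo[1]:sub_hi[1] + 1, sub_lo[2]:sub_hi[2] + 1]
        sub |= inside.reshape(sub.shape).astype(np.uint8)

    voxels = np.where(mask > 0, spec.foreground, spec.background).astype(np.float32)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.noise_seed)
        voxels = voxels + rng.normal(0.0, spec.noise_sd, size=voxels.shape).astype(np.float32)

    vol = ImageVolume(voxels=voxels, spacing=tuple(spacing), origin=tuple(origin))
    bmask = BinaryMask(voxels=mask, spacing=tuple(spacing), origin=tuple(origin))

    gt = PhantomGroundTruth(
        segments={s.name: s for s in spec.segments},
        kappa_true={s.name: s.kappa_true() for s in spec.segments},
        tau_true={s.name: s.tau_true() for s in spec.segments},
        radius_true={s.name: s.radius for s in spec.segments},
        length_true={s.name: s.arc_length() for s in spec.segments},
        angle_true={s.name: s.declared_angle_deg for s in spec.segments
                    if s.declared_angle_deg is not None},
        analytic_volume=sum(s.analytic_volume() for s in spec.segments),
        lesion=spec.resolve_lesion(),
    )
    return vol, bmask, gt


# ---- synthetic cohorts ------------------------------------------------------

# Reference per-feature class distributions for the 16 geometric features that
# separate navigation success from failure in peripheral-airway cohorts:
# name -> ((mean_success, sd_success), (mean_failure, sd_failure)).
TABLE_EFFECTS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "BifurcationAngleIn_Branch0": ((23.174, 11.243), (34.256, 12.971)),
    "SectionalAreaMinimum_Branch0": ((7.139, 3.721), (4.170, 2.384)),
    "MaxInscribedSphereRMinimum_Branch0": ((1.384, 0.294), (1.089, 0.261)),
    "MaxInscribedSphereRAverage_Branch0": ((1.744, 0.282), (1.438, 0.231)),
    "MinDiameterMinimum_Branch0": ((2.670, 0.672), (1.946, 0.643)),
    "MinDiameterAverage_Branch0": ((3.547, 0.753), (2.782, 0.525)),
    "MaxDiameterMinimum_Branch0": ((3.182, 0.836), (2.467, 0.820)),
    "MinMaxDiameterRatioMinimum_Branch2": ((0.269, 0.084), (0.212, 0.101)),
    "MinMaxDiameterRatioMinimum_Branch1": ((0.323, 0.093), (0.259, 0.103)),
    "MinMaxDiameterRatioMaximum_Branch0": ((0.942, 0.055), (0.901, 0.086)),
    "MinMaxDiameterRatioAverage_Branch2": ((0.607, 0.111), (0.539, 0.128)),
    "MinMaxDiameterRatioAverage_Branch0": ((0.737, 0.102), (0.684, 0.091)),
    "CurvatureAverage_Branch0": ((0.193, 0.045), (0.230, 0.041)),
    "TorsionAverage_Branch3": ((0.552, 0.195), (0.792, 0.423)),
    "PerimeterMinimum_Branch0": ((9.430, 2.318), (7.236, 2.174)),
    "LuminalCircularityMinimum_Branch1": ((0.709, 0.082), (0.635, 0.156)),
}


def sample_synthetic_cohort(
    n_success: int,
    n_failure: int,
    effect_spec: dict[str, tuple[tuple[float, float], tuple[float, float]]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a labeled cohort with independent Gaussian features per class.

    ``effect_spec`` maps feature name -> ((mean, sd) success, (mean, sd)
    failure); the default reproduces the reference class distributions of the
    16 discriminative geometric features (``TABLE_EFFECTS``).  The outcome
    column ``failure`` is 1 for the failure (positive) class.
    """
    if n_success <= 0 or n_failure <= 0:
        raise ValueError("group sizes must be positive")
    if effect_spec is None:
        effect_spec = TABLE_EFFECTS
    rng = np.random.default_rng(seed)
    rows = {}
    labels = np.concatenate([np.zeros(n_success, int), np.ones(n_failure, int)])
    for name, ((mu_s, sd_s), (mu_f, sd_f)) in effect_spec.items():
        vals_s = rng.normal(mu_s, sd_s, size=n_success)
        vals_f = rng.normal(mu_f, sd_f, size=n_failure)
        rows[name] = np.concatenate([vals_s, vals_f])
    df = pd.DataFrame(rows)
    df.insert(0, "case_id", [f"case_{i:04d}" for i in range(len(df))])
    df["failure"] = labels
    return df
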