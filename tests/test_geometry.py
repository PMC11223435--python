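"""Surface, skeleton, centerline, Frenet and tree assembly against phantoms."""

import numpy as np
import pytest

from airwaygeom import (
    CenterlinePolyline,
    GeometryError,
    PipelineConfig,
    build_tree,
    detect_root_and_endpoints,
    estimate_frenet,
    extract_centerlines,
    extract_surface,
    frenet_from_points,
)
from airwaygeom.imaging import BinaryMask
from airwaygeom.phantom import (
    PhantomTreeSpec,
    helix,
    rasterize_phantom,
    straight,
    torus_arc,
)


@pytest.fixture(scope="module")
def cylinder_lines(cylinder_phantom):
    _, mask, gt = cylinder_phantom
    mesh = extract_surface(mask)
    root, endpoints = detect_root_and_endpoints(mask)
    lines = extract_centerlines(mesh, mask, root, endpoints)
    return mask, gt, mesh, root, endpoints, lines


class TestSurface:
    def test_cylinder_area_within_5_percent(self, cylinder_lines):
        _, _, mesh, _, _, _ = cylinder_lines
        true = 2 * np.pi * 3.0 * 40.0 + 2 * np.pi * 3.0**2
        assert mesh.area == pytest.approx(true, rel=0.05)

    def test_mesh_is_closed_and_isotropic(self, cylinder_lines):
        _, _, mesh, _, _, _ = cylinder_lines
        assert mesh.is_watertight
        lengths = mesh.edges_unique_length
        assert lengths.max() / lengths.min() <= 4.0

    def test_single_voxel_is_topological_sphere(self):
        vox = np.zeros((5, 5, 5), dtype=np.uint8)
        vox[2, 2, 2] = 1
        mesh = extract_surface(BinaryMask(vox, spacing=(1, 1, 1)))
        assert mesh.euler_number == 2
        assert mesh.is_watertight

    def test_empty_mask_rejected(self):
        with pytest.raises(GeometryError, match="empty"):
            extract_surface(BinaryMask(np.zeros((4, 4, 4), np.uint8), (1, 1, 1)))

    def test_boundary_touching_mask_warns_and_caps(self):
        vox = np.ones((6, 6, 6), dtype=np.uint8)
        with pytest.warns(UserWarning, match="boundary"):
            mesh = extract_surface(BinaryMask(vox, spacing=(1, 1, 1)))
        assert mesh.is_watertight


class TestRootAndEndpoints:
    def test_cylinder_two_termini_root_at_max_z(self, cylinder_phantom):
        _, mask, _ = cylinder_phantom
        root, endpoints = detect_root_and_endpoints(mask)
        assert len(endpoints) == 1
        # tube runs from z = 0 down to z = -40
        assert root[2] > endpoints[0][2]
        assert root[2] > -5.0

    def test_y_phantom_three_candidates(self, y_phantom):
        _, mask, _ = y_phantom
        root, endpoints = detect_root_and_endpoints(mask)
        assert len(endpoints) == 2
        assert root[2] > max(e[2] for e in endpoints)

    def test_sphere_has_no_linear_endpoints(self):
        ax = np.arange(24) * 0.5
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        ball = ((gx - 6) ** 2 + (gy - 6) ** 2 + (gz - 6) ** 2) <= 16.0
        with pytest.raises(GeometryError):
            detect_root_and_endpoints(BinaryMask(ball, spacing=(0.5, 0.5, 0.5)))


class TestCenterlines:
    def test_cylinder_points_on_axis(self, cylinder_lines):
        _, gt, _, _, _, lines = cylinder_lines
        d = gt.distance_to_axis("trunk", lines[0].points)
        # within one voxel diagonal of the true axis
        assert d.max() <= np.linalg.norm([0.5, 0.5, 0.5])

    def test_cylinder_radius_profile(self, cylinder_lines):
        _, _, _, _, _, lines = cylinder_lines
        med = np.median(lines[0].radius)
        assert 3.0 - 0.5 <= med <= 3.0 + 0.5

    def test_torus_arclength_within_5_percent(self):
        spec = PhantomTreeSpec(
            segments=[torus_arc("arc", 3.0, 20.0, 90.0, start=(0, 0, 40),
                                direction=(0, 0, -1), bend_normal=(1, 0, 0))],
            spacing=(0.5, 0.5, 0.5),
        )
        _, mask, _ = rasterize_phantom(spec)
        mesh = extract_surface(mask)
        root, eps = detect_root_and_endpoints(mask)
        line = extract_centerlines(mesh, mask, root, eps)[0]
        assert line.total_length == pytest.approx(np.pi / 2 * 20.0, rel=0.05)

    def test_medialness_no_off_axis_bias(self, cylinder_lines):
        """Centerline clearance beats random interior points in each section."""
        mask, _, mesh, _, _, lines = cylinder_lines
        line = lines[0]
        rng = np.random.default_rng(4)
        from scipy.spatial import cKDTree

        surf = cKDTree(np.asarray(mesh.vertices))
        interior = slice(8, len(line.points) - 8)
        for i in list(range(*interior.indices(len(line.points))))[::10]:
            p = line.points[i]
            t = line.points[i + 1] - line.points[i - 1]
            t /= np.linalg.norm(t)
            u = np.cross(t, [1.0, 0, 0]) if abs(t[0]) < 0.9 else np.cross(t, [0, 0, 1.0])
            u /= np.linalg.norm(u)
            v = np.cross(t, u)
            best = 0.0
            for _ in range(10):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, 2.0)
                q = p + rad * (np.cos(ang) * u + np.sin(ang) * v)
                best = max(best, surf.query(q)[0])
            assert line.radius[i] >= 0.9 * best

    def test_unreachable_endpoint_rejected(self, cylinder_lines):
        mask, _, mesh, root, _, _ = cylinder_lines
        with pytest.raises(GeometryError, match="coincide|unreachable"):
            extract_centerlines(mesh, mask, root, [root])


class TestFrenet:
    def test_circle_arc_closed_form(self):
        arc = torus_arc("a", 3.0, 20.0, 90.0, start=(0, 0, 0),
                        direction=(0, 0, -1), bend_normal=(1, 0, 0))
        pts = arc.curve(np.arange(0, arc.arc_length(), 0.5))
        _, kappa, tau = frenet_from_points(pts, 0.5, 1.0)
        i = slice(6, -6)
        assert kappa[i].mean() == pytest.approx(0.05, rel=0.05)
        assert tau[i].mean() < 1e-3

    def test_straight_line_flat(self):
        pts = np.linspace([0, 0, 0], [0, 0, 30], 61)
        _, kappa, tau = frenet_from_points(pts, 0.5, 1.0)
        assert kappa.max() < 1e-6
        assert tau.max() < 1e-6

    def test_helix_closed_form(self):
        hx = helix("h", 2.0, bend_radius=10.0, pitch=3.0, arc_deg=360.0)
        pts = hx.curve(np.arange(0, hx.arc_length(), 0.5))
        _, kappa, tau = frenet_from_points(pts, 0.5, 1.0)
        i = slice(6, -6)
        assert kappa[i].mean() == pytest.approx(10.0 / 109.0, rel=0.05)
        assert tau[i].mean() == pytest.approx(3.0 / 109.0, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5 points"):
            frenet_from_points(np.zeros((4, 3)), 0.5, 1.0)

    def test_pipeline_curvature_error_converges(self):
        """Torus curvature error decreases monotonically as spacing halves."""
        errs = []
        for sp in (1.0, 0.5, 0.25):
            spec = PhantomTreeSpec(
                segments=[torus_arc("arc", 3.0, 20.0, 90.0, start=(0, 0, 40),
                                    direction=(0, 0, -1), bend_normal=(1, 0, 0))],
                spacing=(sp, sp, sp),
            )
            _, mask, _ = rasterize_phantom(spec)
            mesh = extract_surface(mask)
            root, eps = detect_root_and_endpoints(mask)
            line = estimate_frenet(extract_centerlines(mesh, mask, root, eps)[0])
            # 8 mm interior margin: outside the end extensions plus the
            # derivative smoothing support
            m = int(8.0 / line.step)
            errs.append(abs(line.curvature[m:-m].mean() - 0.05) / 0.05)
        assert errs[0] > errs[1] > errs[2]


class TestTree:
    def test_y_tree_structure(self, y_result):
        tree = y_result.tree
        assert len(tree.sections) == 3
        assert tree.n_bifurcations() == 1
        assert len(tree.leaf_sections()) == 2

    def test_single_polyline_tree(self, cylinder_lines):
        _, _, _, _, _, lines = cylinder_lines
        tree = build_tree([estimate_frenet(lines[0])])
        assert len(tree.sections) == 1
        assert tree.n_bifurcations() == 0
        assert tree.sections[tree.root_section].bifurcation_angle_in is None

    def test_declared_angle_recovered(self, y_result):
        angles = [s.bifurcation_angle_in for s in y_result.tree.sections.values()
                  if s.bifurcation_angle_in is not None]
        assert len(angles) == 2
        for a in angles:
            assert a == pytest.approx(35.0, abs=5.0)

    def test_path_length_conservation(self, y_result):
        """Section lengths along a root->leaf path sum to the polyline length."""
        tree = y_result.tree
        for line in y_result.centerlines:
            leaf_pt = line.points[-1]
            leaf_sid = min(
                tree.leaf_sections(),
                key=lambda s: np.linalg.norm(tree.sections[s].points[-1] - leaf_pt),
            )
            total = sum(tree.sections[s].section_length
                        for s in tree.path_to_root(leaf_sid))
            assert total == pytest.approx(line.total_length, abs=2 * 0.5 + 1.0)

    def test_bifurcation_count_matches_leaves(self, three_gen_result):
        tree = three_gen_result.tree
        assert tree.n_bifurcations() == len(tree.leaf_sections()) - 1

    def test_disjoint_roots_rejected(self):
        a = CenterlinePolyline(
            points=np.linspace([0, 0, 0], [0, 0, 10], 21),
            radius=np.full(21, 2.0), arclength=np.linspace(0, 10, 21),
        )
        b = CenterlinePolyline(
            points=np.linspace([30, 0, 0], [30, 0, 10], 21),
            radius=np.full(21, 2.0), arclength=np.linspace(0, 10, 21),
        )
        with pytest.raises(GeometryError, match="root"):
            build_tree([a, b])
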