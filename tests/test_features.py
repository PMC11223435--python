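"""Cross-section metrics, section aggregation, lesion mapping, path features."""

import numpy as np
import pytest

from airwaygeom import (
    GeometryError,
    PipelineConfig,
    cut_cross_section,
    extract_surface,
    find_branch0,
    path_features,
    section_features,
)
from airwaygeom.features import (
    FAMILIES,
    GLOBAL_FEATURES,
    LOCAL_FEATURES_PER_SECTION,
    STATISTICS,
)
from airwaygeom.geometry import AirwayTree, BranchSection, TreeNode


@pytest.fixture(scope="module")
def cylinder_cut(cylinder_phantom):
    _, mask, _ = cylinder_phantom
    mesh = extract_surface(mask)
    return mask, mesh


class TestCrossSection:
    def test_perpendicular_circle(self, cylinder_cut):
        mask, mesh = cylinder_cut
        cs = cut_cross_section(mask, np.array([0, 0, -20.0]), np.array([0, 0, 1.0]),
                               mesh=mesh)
        assert cs.sectional_area == pytest.approx(np.pi * 9.0, rel=0.05)
        assert cs.luminal_circularity >= 0.95
        assert cs.min_diameter == pytest.approx(6.0, rel=0.05)
        assert cs.max_diameter == pytest.approx(6.0, rel=0.05)
        assert cs.perimeter == pytest.approx(2 * np.pi * 3.0, rel=0.05)

    def test_oblique_60_degree_ellipse(self, cylinder_cut):
        """A cut at 60 degrees to the axis is an ellipse with axes 2r, 2r/cos60."""
        mask, mesh = cylinder_cut
        normal = np.array([np.sin(np.deg2rad(60)), 0.0, np.cos(np.deg2rad(60))])
        cs = cut_cross_section(mask, np.array([0, 0, -20.0]), normal, mesh=mesh)
        assert cs.min_diameter == pytest.approx(6.0, rel=0.05)
        assert cs.max_diameter == pytest.approx(12.0, rel=0.05)
        assert cs.min_max_diameter_ratio == pytest.approx(0.5, abs=0.05)

    def test_point_on_background_rejected(self, cylinder_cut):
        mask, mesh = cylinder_cut
        with pytest.raises(GeometryError, match="not inside"):
            cut_cross_section(mask, np.array([8.0, 8.0, -20.0]),
                              np.array([0, 0, 1.0]), mesh=mesh)


class TestSectionFeatures:
    def test_exactly_38_local_features(self, y_result, y_phantom):
        _, mask, _ = y_phantom
        sec = y_result.tree.sections[y_result.tree.root_section]
        row = section_features(sec, mask, mesh=y_result.mesh)
        values = {k: v for k, v in row.items() if not k.startswith("_")}
        assert len(values) == LOCAL_FEATURES_PER_SECTION == 38
        expected = {"BifurcationAngleIn", "SectionalLength"} | {
            f"{fam}{stat}" for fam in FAMILIES for stat in STATISTICS
        }
        assert set(values) == expected

    def test_cylinder_section_statistics(self, cylinder_phantom):
        from airwaygeom.pipeline import run_pipeline

        _, mask, _ = cylinder_phantom
        res = run_pipeline(mask, lesion=None)
        row = {k.rsplit("_Section", 1)[0]: v for k, v in res.feature_row.items()}
        assert row["CurvatureAverage"] <= 0.01
        assert 5.5 <= row["MinDiameterAverage"] <= 6.5
        # constant tube radius: inscribed-sphere spread below half a voxel
        assert row["MaxInscribedSphereRStdDev"] <= 0.25
        # min <= avg <= max for every family
        for fam in FAMILIES:
            assert row[f"{fam}Minimum"] <= row[f"{fam}Average"] <= row[f"{fam}Maximum"]
            assert row[f"{fam}StdDev"] >= 0.0


def _chain_tree(lengths, angles):
    """Hand-built chain of straight sections along -z (for lesion mapping)."""
    nodes, sections = {}, {}
    z = 0.0
    nodes[0] = TreeNode(0, "root", np.array([0.0, 0.0, 0.0]))
    parent_sid = None
    for i, (L, ang) in enumerate(zip(lengths, angles)):
        pts = np.linspace([0, 0, z], [0, 0, z - L], max(int(L / 0.5) + 1, 2))
        nodes[i + 1] = TreeNode(
            i + 1, "endpoint" if i == len(lengths) - 1 else "bifurcation",
            pts[-1],
        )
        sections[i] = BranchSection(
            id=i, proximal_node=i, distal_node=i + 1, points=pts,
            radius=np.full(len(pts), 2.0), curvature=np.zeros(len(pts)),
            torsion=np.zeros(len(pts)),
            section_length=L, bifurcation_angle_in=ang, parent_section=parent_sid,
        )
        parent_sid = i
        z -= L
    return AirwayTree(nodes=nodes, sections=sections, root_section=0)


class TestBranchNumbering:
    def test_lesion_at_leaf_of_y(self, y_result, y_phantom):
        _, _, gt = y_phantom
        sec, path = find_branch0(y_result.tree, gt.lesion)
        assert sec.id in y_result.tree.leaf_sections()
        assert path[0] == y_result.tree.root_section
        assert path[-1] == sec.id
        assert len(path) == 2

    def test_chain_numbering_against_brute_force(self):
        tree = _chain_tree([30.0, 20.0, 10.0, 8.0], [None, 20.0, 30.0, 40.0])
        lesion = np.array([0.5, 0.0, -67.0])  # near the distal tip
        sec, path = find_branch0(tree, lesion)
        # brute force: nearest centerline point over all sections
        best = min(
            tree.sections.values(),
            key=lambda s: np.linalg.norm(s.points - lesion, axis=1).min(),
        )
        assert sec.id == best.id
        assert path == [0, 1, 2, 3]

    def test_equidistant_lesion_takes_lower_section_id(self):
        tree = _chain_tree([10.0, 10.0], [None, 25.0])
        # exactly on the shared node between sections 0 and 1
        sec, _ = find_branch0(tree, np.array([0.0, 0.0, -10.0]))
        assert sec.id == 0

    def test_distant_lesion_rejected(self):
        tree = _chain_tree([10.0], [None])
        with pytest.raises(GeometryError, match="no leading bronchus"):
            find_branch0(tree, np.array([0.0, 0.0, 200.0]))


class TestPathFeatures:
    def test_total_length_additivity_and_angle_stats(self):
        tree = _chain_tree([30.0, 20.0, 10.0], [None, 20.0, 40.0])
        secs = [tree.sections[i] for i in (0, 1, 2)]
        out = path_features([], secs)
        assert set(out) == set(GLOBAL_FEATURES) and len(out) == 6
        assert out["TotalLength"] == pytest.approx(60.0)
        assert out["BifurcationAngleSum"] == pytest.approx(60.0)
        assert out["BifurcationAngleMinimum"] == pytest.approx(20.0)
        assert out["BifurcationAngleMaximum"] == pytest.approx(40.0)
        assert out["BifurcationAngleAverage"] == pytest.approx(30.0)
        assert out["BifurcationAngleStdDev"] == pytest.approx(np.std([20, 40], ddof=1))

    def test_root_only_path_has_null_angles(self):
        tree = _chain_tree([30.0], [None])
        out = path_features([], [tree.sections[0]])
        assert out["TotalLength"] == pytest.approx(30.0)
        assert out["BifurcationAngleAverage"] is None


class TestCaseRow:
    def test_y_case_emits_full_contract(self, y_result):
        row = y_result.feature_row
        branch0 = [k for k in row if k.endswith("_Branch0")]
        branch1 = [k for k in row if k.endswith("_Branch1")]
        globals_ = [k for k in row if "_Branch" not in k]
        assert len(branch0) == 38
        assert len(branch1) == 38
        assert sorted(globals_) == sorted(GLOBAL_FEATURES)
        # Branch 0 is the distal (child) section: thinner than the trunk
        assert row["MaxInscribedSphereRAverage_Branch0"] < \
            row["MaxInscribedSphereRAverage_Branch1"]
        # root section entry angle is missing, not zero
        assert row["BifurcationAngleIn_Branch1"] is None
        assert row["BifurcationAngleIn_Branch0"] == pytest.approx(35.0, abs=5.0)
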