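"""The phantom oracle itself: closed forms, rasterization, cohorts."""

import numpy as np
import pytest
from scipy import stats

from airwaygeom.phantom import (
    TABLE_EFFECTS,
    PhantomTreeSpec,
    TubeSegmentSpec,
    attach,
    helix,
    rasterize_phantom,
    sample_synthetic_cohort,
    straight,
    torus_arc,
)


class TestSegmentSpecs:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            straight("s", radius=-1.0, length=10.0)
        with pytest.raises(ValueError):
            straight("s", radius=1.0, length=0.0)
        with pytest.raises(ValueError, match="arc_deg"):
            torus_arc("t", radius=1.0, bend_radius=10.0, arc_deg=0.0)
        with pytest.raises(ValueError, match="self-intersecting"):
            torus_arc("t", radius=5.0, bend_radius=4.0, arc_deg=90.0)
        with pytest.raises(ValueError, match="pitch"):
            TubeSegmentSpec(name="h", kind="helix", radius=1.0,
                            start=(0, 0, 0), direction=(0, 1, 0),
                            arc_deg=180.0, bend_radius=5.0)

    def test_closed_form_curvature_torsion(self):
        s = straight("s", 2.0, 10.0)
        assert s.kappa_true() == 0.0 and s.tau_true() == 0.0
        t = torus_arc("t", 2.0, bend_radius=20.0, arc_deg=90.0)
        assert t.kappa_true() == pytest.approx(0.05)
        assert t.tau_true() == 0.0
        h = helix("h", 1.5, bend_radius=10.0, pitch=3.0, arc_deg=360.0)
        assert h.kappa_true() == pytest.approx(10.0 / 109.0)
        assert h.tau_true() == pytest.approx(3.0 / 109.0)

    def test_torus_curve_geometry(self):
        """Sampled torus-arc points lie at bend_radius from the bend center."""
        t = torus_arc("t", 2.0, bend_radius=20.0, arc_deg=90.0,
                      start=(0, 0, 0), direction=(0, 0, -1), bend_normal=(1, 0, 0))
        pts = t.curve(np.linspace(0, t.arc_length(), 50))
        center = np.array([20.0, 0.0, 0.0])
        np.testing.assert_allclose(np.linalg.norm(pts - center, axis=1), 20.0,
                                   atol=1e-9)
        assert t.arc_length() == pytest.approx(np.pi / 2 * 20.0)

    def test_helix_curve_geometry(self):
        """Helix points stay at R from the axis and rise by pitch per radian."""
        h = helix("h", 1.5, bend_radius=10.0, pitch=3.0, arc_deg=360.0,
                  start=(0, 0, 0), bend_normal=(1, 0, 0))
        L = h.arc_length()
        assert L == pytest.approx(2 * np.pi * np.hypot(10.0, 3.0))
        s = np.linspace(0, L, 100)
        pts = h.curve(s)
        # after a full turn the point returns to start + 2*pi*c along the axis
        rise = np.linalg.norm(pts[-1] - pts[0])
        assert rise == pytest.approx(2 * np.pi * 3.0, rel=1e-6)
        # start tangent matches the requested direction
        np.testing.assert_allclose(h.tangent(np.array([0.0]))[0], h.direction,
                                   atol=1e-4)

    def test_attach_declared_angle_is_axis_angle(self):
        trunk = straight("trunk", 3.0, 30.0, direction=(0, 0, -1))
        child = attach(trunk, "c", 2.0, 20.0, angle_deg=35.0, azimuth_deg=40.0)
        cosang = np.dot(trunk.end_tangent(), child.direction)
        assert np.degrees(np.arccos(cosang)) == pytest.approx(35.0, abs=1e-9)
        np.testing.assert_allclose(child.start, trunk.end_point(), atol=1e-12)


class TestRasterization:
    def test_cylinder_volume_within_2_percent(self, cylinder_phantom):
        _, mask, gt = cylinder_phantom
        analytic = np.pi * 3.0**2 * 40.0
        assert gt.analytic_volume == pytest.approx(analytic)
        assert mask.foreground_volume() == pytest.approx(analytic, rel=0.02)

    def test_volume_error_decreases_with_spacing(self):
        errs = []
        for sp in (1.0, 0.5, 0.25):
            seg = straight("s", 3.0, 20.0, direction=(0, 0, -1))
            spec = PhantomTreeSpec(segments=[seg], spacing=(sp, sp, sp))
            _, mask, gt = rasterize_phantom(spec)
            errs.append(abs(mask.foreground_volume() - gt.analytic_volume)
                        / gt.analytic_volume)
        assert errs[0] > errs[1] > errs[2]

    def test_under_resolved_tube_rejected(self):
        seg = straight("s", 1.0, 10.0)
        spec = PhantomTreeSpec(segments=[seg], spacing=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="under-resolved"):
            rasterize_phantom(spec)

    def test_declared_angle_in_ground_truth(self, y_phantom):
        _, _, gt = y_phantom
        assert gt.angle_true == {"c1": 35.0, "c2": 35.0}

    def test_volume_intensities_and_noise_determinism(self):
        seg = straight("s", 3.0, 10.0)
        spec = PhantomTreeSpec(segments=[seg], spacing=(0.5, 0.5, 0.5),
                               foreground=-1000.0, background=0.0,
                               noise_sd=20.0, noise_seed=9)
        vol1, mask, _ = rasterize_phantom(spec)
        vol2, _, _ = rasterize_phantom(spec)
        np.testing.assert_array_equal(vol1.voxels, vol2.voxels)
        fg = vol1.voxels[mask.voxels > 0]
        bg = vol1.voxels[mask.voxels == 0]
        assert fg.mean() == pytest.approx(-1000.0, abs=5.0)
        assert bg.mean() == pytest.approx(0.0, abs=5.0)

    def test_child_must_start_on_parent_end(self):
        trunk = straight("trunk", 3.0, 30.0)
        bad = straight("c", 2.0, 10.0, start=(5, 5, 5), parent="trunk")
        with pytest.raises(ValueError, match="parent"):
            PhantomTreeSpec(segments=[trunk, bad], spacing=(0.5, 0.5, 0.5))


class TestSyntheticCohort:
    def test_deterministic_under_seed(self):
        a = sample_synthetic_cohort(27, 27, seed=11)
        b = sample_synthetic_cohort(27, 27, seed=11)
        assert a.equals(b)
        assert not a.drop(columns=["case_id", "failure"]).equals(
            sample_synthetic_cohort(27, 27, seed=12).drop(columns=["case_id", "failure"])
        )

    def test_nonpositive_group_size_rejected(self):
        with pytest.raises(ValueError):
            sample_synthetic_cohort(0, 5)

    def test_reference_means_recovered(self):
        """Group means land within 3 SE of the reference class parameters."""
        t = sample_synthetic_cohort(400, 400, seed=3)
        for feat in ("MinDiameterAverage_Branch0", "BifurcationAngleIn_Branch0"):
            (mu_s, sd_s), (mu_f, sd_f) = TABLE_EFFECTS[feat]
            g0 = t.loc[t.failure == 0, feat]
            g1 = t.loc[t.failure == 1, feat]
            assert abs(g0.mean() - mu_s) < 3 * sd_s / np.sqrt(len(g0))
            assert abs(g1.mean() - mu_f) < 3 * sd_f / np.sqrt(len(g1))

    def test_null_effect_false_positive_rate(self):
        """With identical class distributions the t-test rejects at ~alpha."""
        null_spec = {"f": ((0.0, 1.0), (0.0, 1.0))}
        rejections = 0
        n_mc = 1000
        for seed in range(n_mc):
            t = sample_synthetic_cohort(15, 15, effect_spec=null_spec, seed=seed)
            _, p = stats.ttest_ind(t.loc[t.failure == 0, "f"],
                                   t.loc[t.failure == 1, "f"])
            rejections += p < 0.05
        rate = rejections / n_mc
        # binomial 99.9% band around 0.05 at n = 1000
        assert 0.028 < rate < 0.075
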