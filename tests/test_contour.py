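"""Examiner-oracle contours, shape features and the rule classifier."""

import numpy as np
import pytest
from scipy.spatial.distance import directed_hausdorff

import keratotype as kt
from keratotype import contour, synth
from keratotype.synth import ClassLabel, Variant


def noiseless(label, seed, variant=None):
    p = kt.sample_params(label, variant, rng_seed=seed)
    p.noise_sd = 0.0
    return p


class TestOracleContour:
    def test_spherical_is_one_nearly_perfect_circle(self):
        pm = kt.make_power_map(noiseless(ClassLabel.SPHERICAL, 1), grid_n=128)
        c = kt.oracle_contour(pm)
        assert c.kind == "peripheral" and len(c.polylines) == 1
        assert contour.circularity(c.polylines[0]) > 0.99

    def test_symmetric_tie_has_two_mirror_lobes(self):
        p = noiseless(ClassLabel.SYMMETRIC, 3)
        pm = kt.make_power_map(p, grid_n=256)
        c = kt.oracle_contour(pm)
        assert len(c.polylines) == 2
        # reflect lobe 1 across the steep axis onto itself: the tie is
        # mirror-symmetric about phi, so each lobe maps onto itself
        a = np.deg2rad(p.axis_phi)
        R = np.array(
            [[np.cos(2 * a), np.sin(2 * a)], [np.sin(2 * a), -np.cos(2 * a)]]
        )
        for lobe in c.polylines:
            refl = lobe @ R.T
            d = max(
                directed_hausdorff(refl, lobe)[0], directed_hausdorff(lobe, refl)[0]
            )
            assert d < 0.15  # mm

    def test_classic_cone_gives_single_inferior_lobe(self):
        for seed in range(5):
            p = noiseless(ClassLabel.IRREGULAR, seed, Variant.CLASSIC_INFERIOR)
            c = kt.oracle_contour(kt.make_power_map(p, grid_n=128))
            assert len(c.polylines) == 1
            assert c.polylines[0][:, 1].mean() < 0.0  # centroid inferior

    def test_flat_surface_is_degenerate_for_tie_trace(self):
        p = noiseless(ClassLabel.SPHERICAL, 1)
        p.label = ClassLabel.SYMMETRIC  # no amplitude: level set empty
        with pytest.raises(contour.DegeneratePatternError):
            kt.oracle_contour(kt.make_power_map(p, grid_n=128), label=ClassLabel.SYMMETRIC)

    def test_contour_json_roundtrip(self):
        pm = kt.make_power_map(noiseless(ClassLabel.SYMMETRIC, 3), grid_n=128)
        c = kt.oracle_contour(pm)
        c2 = contour.Contour.from_json(c.to_json())
        assert c2.level == c.level and len(c2.polylines) == len(c.polylines)
        np.testing.assert_allclose(c2.polylines[0], c.polylines[0])


class TestRasterize:
    def test_empty_contour_rasterizes_to_zeros(self):
        mask = kt.rasterize(contour.Contour(polylines=[]), 64)
        assert not mask.any()

    def test_filled_circle_area_matches_analytic(self):
        ring = contour.peripheral_ring(radius_mm=2.0)
        for n in (64, 256):
            mask = kt.rasterize(contour.Contour([ring]), n, thickness_px=1, fill=True)
            analytic = np.pi * 2.0**2 / 9.0**2
            # the 1-px outline stroke can add up to ~one perimeter of pixels
            perim_frac = 2.0 * np.pi * 2.0 * (n / 9.0) / n**2
            assert abs(mask.mean() - analytic) < 1.2 * perim_frac

    def test_stroke_count_scales_linearly_with_resolution(self):
        ring = contour.peripheral_ring(radius_mm=2.5)
        c = contour.Contour([ring])
        n64 = kt.rasterize(c, 64, thickness_px=1).sum()
        n256 = kt.rasterize(c, 256, thickness_px=1).sum()
        assert n256 / n64 == pytest.approx(4.0, rel=0.15)

    def test_trace_back_recovers_shape(self):
        import skimage.measure

        pm = kt.make_power_map(noiseless(ClassLabel.IRREGULAR, 2, Variant.CLASSIC_INFERIOR), grid_n=128)
        c = kt.oracle_contour(pm)
        n = 128
        mask = kt.rasterize(c, n, thickness_px=1, fill=True)
        traced = max(skimage.measure.find_contours(mask.astype(float), 0.5), key=len)
        # back to px coords of the input polyline
        mm_per_px = 2 * synth.DISC_RADIUS_MM / n
        cc = (n - 1) / 2.0
        orig_px = np.column_stack(
            [cc - c.polylines[0][:, 1] / mm_per_px, cc + c.polylines[0][:, 0] / mm_per_px]
        )
        d = max(
            directed_hausdorff(traced, orig_px)[0], directed_hausdorff(orig_px, traced)[0]
        )
        assert d < 2.0  # px


class TestShapeFeatures:
    def test_symmetric_tie_features(self):
        for seed in range(10):
            f = kt.shape_features(
                kt.oracle_contour(kt.make_power_map(noiseless(ClassLabel.SYMMETRIC, seed), grid_n=128))
            )
            assert f.lobe_count == 2
            assert f.symmetry_ratio > 0.9
            assert abs(f.inter_meridian_angle - 90.0) < 10.0

    def test_asymmetric_ratio_tracks_extent_ratio(self):
        p = noiseless(ClassLabel.ASYMMETRIC, 0)
        p.amp_sup = p.amp_inf = 3.0
        p.radial_extent_inf = 2.0
        p.radial_extent_sup = 1.2  # extent ratio 0.6
        f = kt.shape_features(kt.oracle_contour(kt.make_power_map(p, grid_n=256)))
        assert f.lobe_count == 2
        assert f.symmetry_ratio == pytest.approx(0.6, abs=0.12)
        assert f.symmetry_ratio < 0.75

    def test_single_lobe_counted(self):
        f = kt.shape_features(
            kt.oracle_contour(
                kt.make_power_map(noiseless(ClassLabel.IRREGULAR, 1, Variant.CLASSIC_INFERIOR), grid_n=128)
            )
        )
        assert f.lobe_count == 1

    def test_steep_axis_recovered_for_symmetric_tie(self):
        for seed in (2, 5, 9):
            p = noiseless(ClassLabel.SYMMETRIC, seed)
            f = kt.shape_features(kt.oracle_contour(kt.make_power_map(p, grid_n=128)))
            d = abs(f.steep_axis - p.axis_phi) % 180.0
            assert min(d, 180.0 - d) < 8.0

    def test_symmetry_metric_rotation_invariant(self):
        p = noiseless(ClassLabel.ASYMMETRIC, 7)
        f0 = kt.shape_features(kt.oracle_contour(kt.make_power_map(p, grid_n=128)))
        p.axis_phi = (p.axis_phi + 40.0) % 180.0
        f1 = kt.shape_features(kt.oracle_contour(kt.make_power_map(p, grid_n=128)))
        assert f1.symmetry_ratio == pytest.approx(f0.symmetry_ratio, abs=0.05)


class TestRuleClassify:
    @pytest.mark.parametrize("label", list(ClassLabel))
    def test_noiseless_closed_loop_agreement(self, label):
        for seed in range(50):
            pm = kt.make_power_map(noiseless(label, 100 + seed), grid_n=128)
            got = kt.rule_classify(kt.shape_features(kt.oracle_contour(pm)))
            assert got == label

    def test_default_noise_agreement_at_least_99pct(self):
        hits = total = 0
        for label in ClassLabel:
            for seed in range(100):
                p = kt.sample_params(label, rng_seed=9000 + seed)
                pm = kt.make_power_map(p, grid_n=128)
                got = kt.rule_classify(kt.shape_features(kt.oracle_contour(pm)))
                hits += got == label
                total += 1
        assert hits / total >= 0.99

    def test_threshold_tie_breaks_to_symmetric(self):
        f = contour.ShapeFeatures(
            lobe_count=2, lobe_lengths=[3.0, 2.25], symmetry_ratio=0.75,
            inter_meridian_angle=90.0,
        )
        assert kt.rule_classify(f) == ClassLabel.SYMMETRIC

    def test_rudimentary_tie_is_irregular(self):
        for seed in range(20):
            p = noiseless(ClassLabel.IRREGULAR, 300 + seed, Variant.RUDIMENTARY_TIE)
            pm = kt.make_power_map(p, grid_n=128)
            assert kt.rule_classify(kt.shape_features(kt.oracle_contour(pm))) == ClassLabel.IRREGULAR

    def test_skewed_axes_detected_via_angle(self):
        p = noiseless(ClassLabel.IRREGULAR, 4, Variant.SKEWED)
        f = kt.shape_features(kt.oracle_contour(kt.make_power_map(p, grid_n=128)))
        assert abs(f.inter_meridian_angle - 90.0) > contour.RuleThresholds().perpendicularity_tol_deg
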