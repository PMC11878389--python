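"""Generator: parameter invariants, surface model, rendering, capture."""

import numpy as np
import pytest

import keratotype as kt
from keratotype import synth
from keratotype.synth import ClassLabel, Variant


class TestSampleParams:
    @pytest.mark.parametrize("label", list(ClassLabel))
    def test_class_invariants_hold_over_many_seeds(self, label):
        for seed in range(250):
            p = kt.sample_params(label, rng_seed=seed)
            if label is ClassLabel.SPHERICAL:
                assert p.amp_sup == p.amp_inf == 0.0 and p.cone_dk == 0.0
            elif label is ClassLabel.SYMMETRIC:
                assert p.amp_sup == p.amp_inf
                assert p.radial_extent_sup == p.radial_extent_inf
            elif label is ClassLabel.ASYMMETRIC:
                rel = 1.0 - min(p.radial_extent_sup, p.radial_extent_inf) / max(
                    p.radial_extent_sup, p.radial_extent_inf
                )
                assert rel >= synth.MIN_ASYMMETRY - 1e-12
            else:
                severe = (
                    p.cone_dk > 0
                    or abs(p.skew_deg) >= synth.MIN_SKEW_DEG
                    or p.variant in (Variant.INCOMPLETE_TIE, Variant.RUDIMENTARY_TIE)
                )
                assert severe
            assert p.variant in synth.VARIANTS_BY_LABEL[label]

    def test_spherical_defaults_are_flat(self):
        p = kt.sample_params(ClassLabel.SPHERICAL, Variant.NONE, rng_seed=7)
        assert p.amp_sup == p.amp_inf == p.cone_dk == 0.0

    def test_same_seed_identical(self):
        a = kt.sample_params(ClassLabel.IRREGULAR, rng_seed=5)
        b = kt.sample_params(ClassLabel.IRREGULAR, rng_seed=5)
        assert a == b

    def test_classic_cone_center_is_inferior(self):
        thetas = [
            kt.sample_params(ClassLabel.IRREGULAR, Variant.CLASSIC_INFERIOR, rng_seed=s).cone_theta
            for s in range(1000)
        ]
        frac_inferior = np.mean([np.sin(np.deg2rad(t)) < 0 for t in thetas])
        assert frac_inferior == 1.0

    def test_invalid_variant_for_label_raises(self):
        with pytest.raises(synth.ConfigError):
            kt.sample_params(ClassLabel.SPHERICAL, Variant.PELLUCID, rng_seed=0)

    def test_params_json_roundtrip(self):
        p = kt.sample_params(ClassLabel.IRREGULAR, Variant.PELLUCID, rng_seed=3)
        import json

        q = synth.SurfaceParams.from_dict(json.loads(json.dumps(p.to_dict())))
        assert p == q


class TestEvalPower:
    def test_spherical_noiseless_is_constant(self):
        p = kt.sample_params(ClassLabel.SPHERICAL, Variant.NONE, rng_seed=1)
        p.noise_sd = 0.0
        for r, th in [(0.0, 0.0), (2.0, 45.0), (4.4, 300.0)]:
            assert kt.eval_power(p, r, th) == pytest.approx(p.k0, abs=1e-12)

    def test_symmetric_mirror_about_steep_axis(self):
        for seed in range(20):
            p = kt.sample_params(ClassLabel.SYMMETRIC, rng_seed=seed)
            p.noise_sd = 0.0
            for d in (10.0, 45.0, 90.0, 150.0):
                a = kt.eval_power(p, 2.0, p.axis_phi + d)
                b = kt.eval_power(p, 2.0, p.axis_phi - d)
                assert a == pytest.approx(b, abs=1e-9)

    def test_cone_peak_location_recovered_by_grid_argmax(self):
        p = synth.SurfaceParams(
            label=ClassLabel.IRREGULAR, variant=Variant.CLASSIC_INFERIOR,
            cone_dk=5.0, cone_r=1.8, cone_theta=250.0, cone_sigma=0.9, noise_sd=0.0,
        )
        pm = kt.make_power_map(p, grid_n=256)
        i, j = np.unravel_index(np.argmax(pm.values), pm.values.shape)
        x, y = pm.mm_grid()
        xc = p.cone_r * np.cos(np.deg2rad(p.cone_theta))
        yc = p.cone_r * np.sin(np.deg2rad(p.cone_theta))
        assert abs(x[i, j] - xc) <= pm.mm_per_px
        assert abs(y[i, j] - yc) <= pm.mm_per_px

    def test_out_of_disc_raises(self):
        p = kt.sample_params(ClassLabel.SPHERICAL, rng_seed=0)
        with pytest.raises(synth.DomainError):
            kt.eval_power(p, 4.6, 0.0)


class TestPowerMap:
    def test_spherical_grid_constant(self):
        p = kt.sample_params(ClassLabel.SPHERICAL, Variant.NONE, rng_seed=2)
        p.noise_sd = 0.0
        pm = kt.make_power_map(p, grid_n=64)
        assert np.allclose(pm.values[pm.mask], p.k0)

    def test_masked_area_matches_analytic_disc(self):
        p = kt.sample_params(ClassLabel.SPHERICAL, rng_seed=0)
        for n in (64, 256):
            pm = kt.make_power_map(p, grid_n=n)
            frac = pm.mask.mean()
            assert frac == pytest.approx(np.pi / 4.0, rel=0.02)

    def test_resolution_consistency(self):
        p = kt.sample_params(ClassLabel.SYMMETRIC, rng_seed=4)
        p.noise_sd = 0.0
        lo = kt.make_power_map(p, grid_n=64)
        hi = kt.make_power_map(p, grid_n=256)
        block = hi.values.reshape(64, 4, 64, 4).mean(axis=(1, 3))
        inner = lo.mask & (np.hypot(*lo.mm_grid()) < 4.0)  # away from the rim
        assert np.max(np.abs(block[inner] - lo.values[inner])) < 0.05

    def test_small_grid_rejected(self):
        with pytest.raises(synth.ConfigError):
            kt.make_power_map(kt.sample_params(ClassLabel.SPHERICAL, rng_seed=0), grid_n=32)


class TestRender:
    def test_constant_map_renders_single_green_hue(self, color_scale):
        p = synth.SurfaceParams(label=ClassLabel.SPHERICAL, k0=43.5, noise_sd=0.0)
        pm = kt.make_power_map(p, grid_n=128)
        topo = kt.render_topogram(pm, color_scale)
        bins = synth.invert_colors_to_bins(topo.image, color_scale)
        disc_bins = bins[pm.mask & (bins >= 0)]
        assert len(np.unique(disc_bins)) == 1
        r, g, b = color_scale.colors[disc_bins[0]]
        assert g > r and g > b  # normal cornea sits in the green band

    def test_two_power_levels_give_two_colors(self, color_scale):
        p = synth.SurfaceParams(label=ClassLabel.SPHERICAL, k0=43.0, noise_sd=0.0)
        pm = kt.make_power_map(p, grid_n=128)
        x, _ = pm.mm_grid()
        pm.values = pm.values + np.where(x > 0, color_scale.step, 0.0)
        topo = kt.render_topogram(pm, color_scale)
        bins = synth.invert_colors_to_bins(topo.image, color_scale)
        assert len(np.unique(bins[pm.mask & (bins >= 0)])) == 2

    def test_color_lut_inversion_matches_power_bins(self, color_scale, symmetric_topogram):
        p = kt.sample_params(ClassLabel.SYMMETRIC, rng_seed=2)
        pm = kt.make_power_map(p)
        topo = kt.render_topogram(pm, color_scale)
        back = synth.invert_colors_to_bins(topo.image, color_scale)
        ok = pm.mask & (back >= 0)
        assert ok.mean() > 0.5  # overlay and background excluded
        assert np.array_equal(back[ok], color_scale.bin_of(pm.values)[ok])

    def test_zone_radii_proportional_3_5_7(self, symmetric_topogram):
        z = np.asarray(symmetric_topogram.zones_px)
        np.testing.assert_allclose(z / z[0], [1.0, 5.0 / 3.0, 7.0 / 3.0], rtol=1e-12)


class TestDistortCapture:
    def test_zero_jitter_is_identity(self, symmetric_topogram):
        img, quad = kt.distort_capture(
            symmetric_topogram, corner_jitter_px=0, photometric={}, rng_seed=5
        )
        assert np.array_equal(img, symmetric_topogram.image)
        assert np.array_equal(quad, synth.frame_corners(symmetric_topogram.image.shape[0]))

    def test_same_seed_byte_identical(self, symmetric_topogram):
        a = kt.distort_capture(symmetric_topogram, rng_seed=9)
        b = kt.distort_capture(symmetric_topogram, rng_seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_quad_is_convex(self, symmetric_topogram):
        for seed in range(10):
            _, quad = kt.distort_capture(symmetric_topogram, corner_jitter_px=25, rng_seed=seed)
            assert synth._is_convex(quad)


class TestGenerateBank:
    def test_single_image_goes_to_train(self, tmp_path):
        rows = synth.generate_bank({ClassLabel.SPHERICAL: 1}, seed=0, out_dir=tmp_path, grid_n=64)
        assert len(rows) == 1 and rows[0]["split"] == "train"
        assert (tmp_path / rows[0]["file"]).exists()
        assert (tmp_path / "manifest.tsv").exists()

    def test_same_seed_identical_manifest(self):
        counts = {lab: 4 for lab in kt.CLASS_ORDER}
        a = synth.generate_bank(counts, seed=3, out_dir=None, write_images=False)
        b = synth.generate_bank(counts, seed=3, out_dir=None, write_images=False)
        assert synth.manifest_digest(a) == synth.manifest_digest(b)

    def test_sidecar_roundtrips_params(self, small_bank):
        import json

        bank, rows = small_bank
        meta = json.loads((bank / rows[0]["file"]).with_suffix(".json").read_text())
        p = synth.SurfaceParams.from_dict(meta["params"])
        q = kt.sample_params(p.label, rng_seed=int(rows[0]["seed"]))
        assert p == q
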