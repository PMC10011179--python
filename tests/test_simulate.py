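"""Synthetic leaf-cube generator: spectral shape, noise and pairing contracts."""

import numpy as np
import pytest

import hsidrought as hd
from hsidrought.simulate import STAGES, red_edge_position


class TestBaseSpectrum:
    @pytest.mark.parametrize("stage", STAGES)
    def test_green_peak_reflectance_strictly_increases_with_stress(self, stage, small_params):
        wl = small_params.wavelengths()
        i560 = int(np.argmin(np.abs(wl - 560)))
        vals = [hd.base_spectrum(lv, stage, small_params)[i560] for lv in (0, 1, 2)]
        assert vals[0] < vals[1] < vals[2]

    def test_zero_effect_gains_collapse_all_levels(self, small_params):
        from dataclasses import replace
        p = replace(small_params, green_peak_gain_per_level=0.0,
                    rededge_blueshift_per_level=0.0)
        specs = [hd.base_spectrum(lv, "young", p) for lv in (0, 1, 2)]
        assert np.array_equal(specs[0], specs[1]) and np.array_equal(specs[1], specs[2])

    @pytest.mark.parametrize("stage", STAGES)
    def test_red_edge_blue_shift_matches_parameter(self, stage, small_params):
        # derived oracle: locate the argmax finite-difference derivative on the grid
        wl = small_params.wavelengths()
        spacing = wl[1] - wl[0]
        pos0 = red_edge_position(hd.base_spectrum(0, stage, small_params), wl)
        pos2 = red_edge_position(hd.base_spectrum(2, stage, small_params), wl)
        expected_shift = 2 * small_params.rededge_blueshift_per_level
        assert pos2 < pos0
        assert abs((pos0 - pos2) - expected_shift) <= spacing

    def test_nir_plateau_is_high_and_visible_baseline_low(self, small_params):
        wl = small_params.wavelengths()
        s = hd.base_spectrum(0, "young", small_params)
        assert s[(wl >= 780)].min() > 0.4
        assert s[(wl >= 430) & (wl <= 500)].max() < 0.25

    @pytest.mark.parametrize("bad", [-1, 3, 1.5])
    def test_invalid_stress_level_rejected(self, bad, small_params):
        with pytest.raises(ValueError, match="stress level"):
            hd.base_spectrum(bad, "young", small_params)

    def test_stage_profiles_differ(self, small_params):
        young = hd.base_spectrum(1, "young", small_params)
        mature = hd.base_spectrum(1, "mature", small_params)
        assert not np.allclose(young, mature)


class TestRenderCube:
    def test_zero_noise_reproduces_spectrum_exactly(self, small_params):
        from dataclasses import replace
        p = replace(small_params, pixel_noise_sd=0.0)
        spec = hd.base_spectrum(0, "young", p)
        cube, mask = hd.render_cube(spec, p, rng_seed=5)
        assert np.allclose(cube.data[mask], spec, atol=1e-6)

    def test_in_mask_mean_within_standard_error(self, small_params):
        spec = hd.base_spectrum(1, "young", small_params)
        cube, mask = hd.render_cube(spec, small_params, rng_seed=11)
        n = mask.sum()
        dev = np.abs(cube.data[mask].mean(axis=0) - spec)
        se = small_params.pixel_noise_sd / np.sqrt(n)
        # per-band 3*SE holds for nearly all of the 128 bands; the max
        # over bands stays within the expected extreme-value range
        assert np.mean(dev <= 3 * se) >= 0.98
        assert dev.max() <= 4.5 * se

    def test_background_is_dark_in_nir(self, small_params):
        spec = hd.base_spectrum(0, "young", small_params)
        cube, mask = hd.render_cube(spec, small_params, rng_seed=3)
        wl = small_params.wavelengths()
        nir = cube.data[~mask][:, wl >= 780]
        assert nir.max() < 0.05

    def test_same_seed_bit_identical(self, small_params):
        spec = hd.base_spectrum(2, "mature", small_params)
        c1, m1 = hd.render_cube(spec, small_params, rng_seed=9)
        c2, m2 = hd.render_cube(spec, small_params, rng_seed=9)
        assert np.array_equal(c1.data, c2.data) and np.array_equal(m1, m2)

    def test_oversized_ellipse_rejected(self, small_params):
        from dataclasses import replace
        p = replace(small_params, leaf_shape=(40, 40))
        with pytest.raises(ValueError, match="does not fit"):
            hd.render_cube(hd.base_spectrum(0, "young", p), p, rng_seed=0)


class TestReferenceFrames:
    def test_white_exceeds_dark_everywhere(self, small_params):
        refs = hd.make_reference_frames(small_params)
        assert np.all(refs.white > refs.dark)

    def test_calibration_recovers_framed_reflectance(self, small_params):
        # raw synthesized as dark + r*(white - dark) must calibrate back to r
        refs = hd.make_reference_frames(small_params)
        spec = hd.base_spectrum(1, "young", small_params)
        cube, _ = hd.render_cube(spec, small_params, rng_seed=2)
        raw = hd.frame_raw(cube, refs)
        back = hd.calibrate(raw, refs)
        assert np.allclose(back.data, cube.data, atol=1e-5)

    def test_zero_ripple_gives_spatially_constant_white(self, small_params):
        from dataclasses import replace
        p = replace(small_params, ripple_amplitude=0.0)
        refs = hd.make_reference_frames(p)
        assert np.allclose(refs.white, refs.white[0:1, :])


class TestGenerateDataset:
    def test_full_design_yields_630_cubes(self, tiny_params):
        ds = hd.generate_dataset((108, 105, 102), tiny_params)
        assert len(ds) == 630
        assert sum(s == "young" for s in ds.stages) == 315

    def test_tiny_design_arithmetic(self, tiny_params):
        ds = hd.generate_dataset((2, 2, 2), tiny_params)
        assert len(ds) == 12
        assert len({ds.pair_key(i) for i in ds.stage_indices("young")}) == 6

    def test_young_mature_pairing_is_total(self, tiny_params):
        ds = hd.generate_dataset((4, 3, 2), tiny_params)
        young = {ds.pair_key(i) for i in ds.stage_indices("young")}
        mature = {ds.pair_key(i) for i in ds.stage_indices("mature")}
        assert young == mature
        assert len(young) == 9  # no duplicate (plant, replicate) within a stage

    def test_same_seed_reproducible(self, tiny_params):
        d1 = hd.generate_dataset((2, 2, 2), tiny_params, seed=4)
        d2 = hd.generate_dataset((2, 2, 2), tiny_params, seed=4)
        assert all(np.array_equal(a.data, b.data) for a, b in zip(d1.cubes, d2.cubes))

    def test_class_mean_spectra_ordered_at_green_peak(self, small_params):
        # monotone stress signal on noiseless spectra
        wl = small_params.wavelengths()
        i560 = int(np.argmin(np.abs(wl - 560)))
        for stage in STAGES:
            m = [hd.base_spectrum(lv, stage, small_params)[i560] for lv in (0, 1, 2)]
            assert m[0] < m[1] < m[2]

    def test_invalid_counts_rejected(self, tiny_params):
        with pytest.raises(ValueError, match="counts"):
            hd.generate_dataset((2, 0, 2), tiny_params)
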