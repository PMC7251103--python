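import io

import numpy as np
import pytest

from sawdesign.acoustics import (
    FieldSolver,
    SimConfig,
    _swf_values,
    binarize,
    compute_pressure,
    design_region,
    load_field,
    pattern_spacing,
    rasterize_shape,
    save_field,
    saw_boundary_condition,
    spherical_wave_kernel,
    wavenumber,
)
from sawdesign.shapes import FourierShape

from conftest import measure_nodal_spacing


class TestSimConfig:
    def test_derived_quantities(self, default_config):
        cfg = default_config
        assert cfg.frequency == pytest.approx(cfg.substrate_sound_speed / cfg.saw_wavelength)
        assert cfg.fluid_wavelength == pytest.approx(
            cfg.fluid_sound_speed * cfg.saw_wavelength / cfg.substrate_sound_speed
        )
        assert cfg.grid_center == (149, 149)
        # fluid-loading attenuation default is positive and of order 1e3 /m
        assert 100 < cfg.attenuation < 1e5

    @pytest.mark.parametrize(
        "kw",
        [
            {"saw_wavelength": 1e-6},  # unresolved on the grid
            {"design_region_size": 400},  # exceeds grid
            {"design_region_size": 150},  # even
            {"pixel_pitch": -1.0},
            {"rolloff_unit": "furlong"},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)

    def test_yaml_roundtrip(self, default_config):
        text = default_config.to_yaml()
        assert SimConfig.from_yaml(io.StringIO(text)) == default_config


class TestPatternSpacing:
    def test_rigid_substrate_limit(self):
        # c_f/c_s -> 0: no refraction, spacing equals the fluid wavelength
        assert pattern_spacing(0.7, 1.0, 1.0, 1e9) == pytest.approx(1.0, rel=1e-6)

    def test_equal_sound_speeds_degenerate(self):
        assert pattern_spacing(np.pi / 4, 1.0, 1500.0, 1500.0) == np.inf

    def test_water_on_lithium_niobate_wall_parallel(self):
        # independent scalar evaluation: 1 / cos(asin(1490/3990)) = 1.07797
        assert pattern_spacing(np.pi / 2, 1.0, 1490.0, 3990.0) == pytest.approx(1.0780, abs=2e-4)

    def test_supersonic_fluid_rejected(self):
        with pytest.raises(ValueError, match="refraction"):
            pattern_spacing(np.pi / 2, 1.0, 2000.0, 1000.0)

    def test_theta_domain(self):
        with pytest.raises(ValueError):
            pattern_spacing(0.0, 1.0, 1490.0, 3990.0)

    def test_wavenumber(self):
        assert wavenumber(0.5) == 2.0
        assert wavenumber(0.5, angular=True) == pytest.approx(4 * np.pi)
        with pytest.raises(ValueError):
            wavenumber(0.0)


class TestBoundaryCondition:
    def test_no_decay_gives_constant_magnitude(self, toy_config):
        cfg = toy_config.replace(attenuation=0.0)
        mask = np.zeros(cfg.grid_shape, dtype=bool)
        mask[4:28, 6:30] = True
        bc = saw_boundary_condition(mask, cfg)
        expected = cfg.angular_frequency * cfg.displacement_amplitude
        np.testing.assert_allclose(np.abs(bc[mask]), expected, rtol=1e-12)
        assert np.all(bc[~mask] == 0)

    def test_leading_edge_magnitude_with_decay(self, toy_config):
        mask = np.zeros(toy_config.grid_shape, dtype=bool)
        mask[10:20, 5:25] = True
        bc = saw_boundary_condition(mask, toy_config)
        lead = np.abs(bc[10:20, 5])
        expected = toy_config.angular_frequency * toy_config.displacement_amplitude
        np.testing.assert_allclose(lead, expected, rtol=1e-12)
        # attenuation strictly reduces magnitude downstream
        assert np.all(np.abs(bc[10:20, 24]) < lead)

    def test_periodic_phase_along_propagation(self):
        # pixels one SAW wavelength apart in x carry identical values (alpha=0)
        cfg = SimConfig(grid_shape=(16, 64), design_region_size=9, attenuation=0.0)
        px_per_wavelength = int(round(cfg.saw_wavelength / cfg.pixel_pitch))
        mask = np.ones(cfg.grid_shape, dtype=bool)
        bc = saw_boundary_condition(mask, cfg)
        np.testing.assert_allclose(bc[:, 0], bc[:, px_per_wavelength], rtol=1e-9)

    def test_grid_mismatch_raises(self, toy_config):
        with pytest.raises(ValueError, match="grid"):
            saw_boundary_condition(np.ones((8, 8), dtype=bool), toy_config)


class TestSphericalWaveKernel:
    def test_center_normalized_to_unity(self, toy_config):
        kernel = spherical_wave_kernel(toy_config, support_radius=50)
        assert kernel[50, 50] == pytest.approx(1.0 + 0j)

    def test_one_pixel_magnitude(self, toy_config):
        kernel = spherical_wave_kernel(toy_config, support_radius=50)
        assert abs(kernel[50, 51]) == pytest.approx(0.5)

    def test_full_cycle_at_fluid_wavelength(self):
        # c_f, c_s, lambda_SAW chosen so lambda_l is exactly 8 pixels: the
        # phase returns to zero there and the value is real positive
        cfg = SimConfig(
            grid_shape=(32, 32), design_region_size=15, pixel_pitch=2e-6,
            saw_wavelength=64e-6, fluid_sound_speed=1000.0, substrate_sound_speed=4000.0,
        )
        assert cfg.fluid_wavelength == pytest.approx(16e-6)
        kernel = spherical_wave_kernel(cfg, support_radius=50)
        assert kernel[50, 58] == pytest.approx(1.0 / 9.0 + 0j, abs=1e-12)

    def test_physical_rolloff_unit(self):
        cfg = SimConfig(grid_shape=(32, 32), design_region_size=15, rolloff_unit="physical")
        kernel = spherical_wave_kernel(cfg, support_radius=10)
        # 1 px = 2 um: denominator is 1 + 2e-6, not 2
        assert abs(kernel[10, 11]) == pytest.approx(1.0 / (1.0 + cfg.pixel_pitch))


class TestComputePressure:
    def test_empty_mask_rejected(self, toy_config):
        with pytest.raises(ValueError, match="empty"):
            compute_pressure(np.zeros(toy_config.grid_shape, dtype=bool), toy_config)

    def test_matches_brute_force_superposition(self, toy_config):
        # independent O(n^4) oracle: explicit sum over all source/target pairs
        cfg = SimConfig(grid_shape=(40, 40), design_region_size=15)
        rng = np.random.default_rng(8)
        mask = np.zeros(cfg.grid_shape, dtype=bool)
        mask[5:35, 4:37] = True
        mask[12:18, 10:16] = False  # interior obstruction
        mask &= rng.random(cfg.grid_shape) > 0.05  # ragged edges
        bc = saw_boundary_condition(mask, cfg)
        rows, cols = cfg.grid_shape
        oracle = np.zeros((rows, cols), dtype=complex)
        rr = np.arange(rows)
        cc = np.arange(cols)
        for tr in range(rows):
            for tc in range(cols):
                dr = (tr - rr)[:, None].astype(float)
                dc = (tc - cc)[None, :].astype(float)
                oracle[tr, tc] = np.sum(bc * _swf_values(dr, dc, cfg))
        amp_oracle = 0.5 * np.abs(oracle)
        amp_oracle[~mask] = 0.0
        fld = compute_pressure(mask, cfg)
        assert np.abs(fld.amplitude - amp_oracle).max() <= 1e-10 * amp_oracle.max()

    def test_linearity_in_displacement_amplitude(self, toy_config):
        mask = np.zeros(toy_config.grid_shape, dtype=bool)
        mask[6:28, 4:30] = True
        amp1 = compute_pressure(mask, toy_config).amplitude
        amp2 = compute_pressure(mask, toy_config.replace(displacement_amplitude=2.0)).amplitude
        np.testing.assert_allclose(amp2, 2.0 * amp1, rtol=1e-12)

    def test_mirror_symmetry(self, default_config, default_solver):
        # mask symmetric about the horizontal centerline -> symmetric field
        shape = FourierShape(2 * 1.3 * default_config.design_half_diagonal,
                             np.array([2e-5, 0.0, 1e-5]), np.zeros(3))
        mask = rasterize_shape(shape, default_config)
        sym = mask | mask[::-1]
        sym = sym & sym[::-1]
        amp = compute_pressure(sym, default_config, default_solver).amplitude
        asym = np.abs(amp - amp[::-1]).max() / amp.max()
        assert asym <= 1e-9

    def test_translation_covariance_perpendicular_to_saw(self):
        cfg = SimConfig(grid_shape=(96, 48), design_region_size=15)
        mask = np.zeros(cfg.grid_shape, dtype=bool)
        mask[30:50, 10:40] = True
        amp = compute_pressure(mask, cfg).amplitude
        dy = 7
        shifted = np.roll(mask, dy, axis=0)
        amp_shifted = compute_pressure(shifted, cfg).amplitude
        np.testing.assert_allclose(amp_shifted[30 + dy : 50 + dy], amp[30:50], rtol=1e-9)

    def test_amplitude_definition(self, toy_config):
        mask = np.ones(toy_config.grid_shape, dtype=bool)
        fld = compute_pressure(mask, toy_config)
        np.testing.assert_allclose(
            fld.amplitude, 0.5 * np.sqrt(fld.complex_field * fld.complex_field.conj()).real
        )

    @pytest.mark.parametrize("theta_deg", [30, 45, 60, 90])
    def test_nodal_spacing_matches_analytic_law(self, theta_deg, default_config, default_solver):
        # core physics link: measured minima spacing next to a flat wall
        # agrees with the analytic diffraction formula within one pixel
        cfg = default_config
        measured = measure_nodal_spacing(np.deg2rad(theta_deg), cfg, default_solver)
        predicted = pattern_spacing(
            np.deg2rad(theta_deg), cfg.fluid_wavelength,
            cfg.fluid_sound_speed, cfg.substrate_sound_speed,
        ) / cfg.pixel_pitch
        assert abs(measured - predicted) <= 1.0


class TestDesignRegion:
    def test_centered_crop_indices(self):
        raster = np.arange(300 * 300, dtype=float).reshape(300, 300)
        crop = design_region(raster, 151)
        assert crop.shape == (151, 151)
        assert crop[0, 0] == raster[74, 74]
        assert crop[-1, -1] == raster[224, 224]

    def test_constant_field_crops_constant(self):
        crop = design_region(np.full((300, 300), 3.5), 151)
        assert np.all(crop == 3.5)

    def test_reembedding_roundtrip(self):
        rng = np.random.default_rng(0)
        raster = rng.random((300, 300))
        crop = design_region(raster, 151)
        re = raster.copy()
        re[74:225, 74:225] = crop
        np.testing.assert_array_equal(re, raster)

    def test_oversized_crop_rejected(self):
        with pytest.raises(ValueError):
            design_region(np.zeros((100, 100)), 151)


class TestBinarize:
    def test_threshold_rule(self):
        np.testing.assert_array_equal(
            binarize(np.array([0.0, 0.5, 1.0])), [False, False, True]
        )

    def test_constant_raster_all_true(self):
        assert binarize(np.full((4, 4), 2.0)).all()

    def test_zero_fraction_keeps_positive_pixels(self):
        np.testing.assert_array_equal(
            binarize(np.array([0.0, 0.1, 1.0]), threshold_fraction=0.0), [False, True, True]
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            binarize(np.zeros((3, 3)))

    def test_maximum_always_included(self):
        rng = np.random.default_rng(1)
        raster = rng.random((20, 20))
        out = binarize(raster)
        assert out[np.unravel_index(raster.argmax(), raster.shape)]


def test_field_hdf5_roundtrip(tmp_path, toy_config):
    mask = np.zeros(toy_config.grid_shape, dtype=bool)
    mask[4:28, 3:29] = True
    fld = compute_pressure(mask, toy_config)
    path = tmp_path / "field.h5"
    save_field(fld, path)
    back = load_field(path)
    np.testing.assert_array_equal(back.amplitude, fld.amplitude)
    np.testing.assert_array_equal(back.complex_field, fld.complex_field)
    np.testing.assert_array_equal(back.channel_mask, fld.channel_mask)
    assert back.config == fld.config


def test_solver_reuse_matches_fresh_solver(toy_config):
    mask = np.zeros(toy_config.grid_shape, dtype=bool)
    mask[8:25, 6:27] = True
    solver = FieldSolver(toy_config)
    a = compute_pressure(mask, toy_config, solver).amplitude
    b = compute_pressure(mask, toy_config).amplitude
    np.testing.assert_array_equal(a, b)
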