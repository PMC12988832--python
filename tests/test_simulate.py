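"""Synthetic scene, forward model, truth masks, and metric-group sampling."""

import numpy as np
import pytest
from scipy.signal import hilbert

from pavis.acquisition import AcquisitionParams, ImageGrid
from pavis.simulate import (
    GroupSpec,
    PhantomScene,
    make_phantom,
    make_truth_masks,
    sample_metric_groups,
    simulate_channel_data,
)
from pavis.stats import kruskal_wallis


class TestMakePhantom:
    def test_minimal_single_absorber_scene(self):
        scene = make_phantom({"absorbers": [[0.0, 10.0, 1.0]], "noise_sigma": 0.0})
        assert scene.absorbers.shape == (1, 3)
        assert scene.noise_sigma == 0.0

    def test_lumen_absorbers_lie_inside_ellipse(self):
        cfg = {
            "lumen": {
                "center": [2.0, 8.0],
                "half_widths": [2.0, 1.0],
                "n_absorbers": 30,
            },
            "seed": 7,
        }
        scene = make_phantom(cfg)
        x, z, _ = scene.absorbers.T
        inside = ((x - 2.0) / 2.0) ** 2 + ((z - 8.0) / 1.0) ** 2
        assert (inside <= 1.0).all()
        assert scene.absorbers.shape[0] == 30

    def test_same_config_same_seed_is_deterministic(self):
        cfg = {
            "lumen": {"center": [0.0, 8.0], "half_widths": [2.0, 1.0], "n_absorbers": 10},
            "seed": 3,
        }
        a = make_phantom(cfg)
        b = make_phantom(cfg)
        np.testing.assert_array_equal(a.absorbers, b.absorbers)

    @pytest.mark.parametrize(
        "absorbers",
        [
            [[0.0, -1.0, 1.0]],  # negative depth
            [[0.0, 0.0, 1.0]],  # zero depth
            [[30.0, 10.0, 1.0]],  # beyond lateral aperture extent +/- 50%
        ],
    )
    def test_rejects_out_of_field_absorbers(self, absorbers):
        with pytest.raises(ValueError):
            make_phantom({"absorbers": absorbers})

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            PhantomScene(absorbers=np.array([[0.0, 5.0, 1.0]]), noise_sigma=-0.1)


class TestSimulateChannelData:
    def test_envelope_peak_matches_time_of_flight_per_element(self, mid_params):
        """Noise-free single absorber: per-element envelope-peak sample index
        equals round(fs * r_e / c) within one sample."""
        scene = make_phantom({"absorbers": [[0.0, 10.0, 1.0]]}, mid_params)
        frame = simulate_channel_data(scene, mid_params)
        env = np.abs(hilbert(frame.data, axis=0))
        peaks = env.argmax(axis=0)
        r_mm = np.sqrt(mid_params.element_positions_mm**2 + 10.0**2)
        expected = np.round(
            r_mm / (mid_params.speed_of_sound_m_s * 1e3) * mid_params.sampling_frequency_hz
        )
        assert (np.abs(peaks - expected) <= 1).all()

    def test_no_absorbers_no_noise_gives_zero_data(self, mid_params):
        scene = PhantomScene(absorbers=np.empty((0, 3)), noise_sigma=0.0)
        frame = simulate_channel_data(scene, mid_params)
        assert not frame.data.any()

    def test_noise_only_sample_std(self):
        params = AcquisitionParams(
            n_elements=8, pitch_mm=0.09, aperture_width_mm=0.72, n_samples=4096
        )
        scene = PhantomScene(absorbers=np.empty((0, 3)), noise_sigma=0.1, seed=5)
        frame = simulate_channel_data(scene, params)
        stds = frame.data.std(axis=0)
        np.testing.assert_allclose(stds, 0.1, rtol=0.05)

    def test_amplitude_linearity(self, mid_params):
        base = make_phantom({"absorbers": [[0.5, 8.0, 1.0], [-1.0, 6.0, 0.5]]}, mid_params)
        doubled = PhantomScene(absorbers=base.absorbers * np.array([1, 1, 2.0]))
        f1 = simulate_channel_data(base, mid_params)
        f2 = simulate_channel_data(doubled, mid_params)
        np.testing.assert_array_equal(f2.data, 2.0 * f1.data)

    def test_absorber_beyond_window_errors(self):
        params = AcquisitionParams(
            n_elements=8, pitch_mm=0.09, aperture_width_mm=0.72, n_samples=64
        )
        scene = PhantomScene(absorbers=np.array([[0.0, 10.0, 1.0]]))
        with pytest.raises(ValueError, match="time of flight"):
            simulate_channel_data(scene, params)

    def test_determinism_with_noise(self, mid_params):
        scene = make_phantom(
            {"absorbers": [[0.0, 8.0, 1.0]], "noise_sigma": 0.2, "seed": 9}, mid_params
        )
        a = simulate_channel_data(scene, mid_params)
        b = simulate_channel_data(scene, mid_params)
        np.testing.assert_array_equal(a.data, b.data)


class TestTruthMasks:
    def test_no_lumen_region_gives_empty_lumen_mask(self, mid_params, mid_grid):
        scene = make_phantom({"absorbers": [[0.0, 8.0, 1.0]]}, mid_params)
        lumen, signal = make_truth_masks(scene, mid_grid, mid_params)
        assert not lumen.any()
        assert signal.any()

    def test_absorber_pixel_inside_signal_mask(self, mid_params, mid_grid):
        x, z = float(mid_grid.lateral_mm[30]), float(mid_grid.axial_mm[400])
        scene = make_phantom({"absorbers": [[x, z, 1.0]]}, mid_params)
        _, signal = make_truth_masks(scene, mid_grid, mid_params)
        assert signal[400, 30]

    def test_ellipse_mask_area_matches_analytic(self, mid_params, mid_grid):
        hw, hd = 1.5, 0.8
        cfg = {
            "lumen": {"center": [0.0, 8.0], "half_widths": [hw, hd], "n_absorbers": 3},
            "seed": 0,
        }
        scene = make_phantom(cfg, mid_params)
        lumen, _ = make_truth_masks(scene, mid_grid, mid_params)
        dz, dx = mid_grid.pixel_size_mm
        measured = lumen.sum() * dz * dx
        analytic = np.pi * hw * hd
        assert abs(measured - analytic) / analytic < 0.10


class TestSampleMetricGroups:
    def test_constant_group_when_scale_zero(self):
        spec = GroupSpec(groups=((10.0, 5, "normal", 4.2, 0.0),))
        out = sample_metric_groups(spec, seed=1)
        np.testing.assert_array_equal(out[10.0], np.full(5, 4.2))

    def test_medians_track_spec_at_moderate_n(self):
        medians = (3.46, 11.43, 9.0, 5.0, 3.5, 6.0)
        ns = (40, 43, 40, 64, 48, 65)
        spec = GroupSpec(
            groups=tuple(
                (float(10 * (i + 1)), n, "normal", m, 0.8)
                for i, (m, n) in enumerate(zip(medians, ns))
            )
        )
        out = sample_metric_groups(spec, seed=42)
        for (label, _, _, med, _) in spec.groups:
            assert abs(np.median(out[label]) - med) < 0.5

    def test_null_type_i_error_near_alpha(self):
        """Identical distributions in two groups: the omnibus rank test
        rejects at roughly the nominal rate over repeated seeds."""
        spec = GroupSpec(
            groups=((1.0, 50, "normal", 0.0, 1.0), (2.0, 50, "normal", 0.0, 1.0))
        )
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            groups = sample_metric_groups(spec, seed=seed)
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        rate = rejections / n_rep
        assert 0.01 <= rate <= 0.10  # ~3 sigma binomial band around 0.05

    def test_reproducible_by_seed(self):
        spec = GroupSpec(groups=((1.0, 10, "lognormal", 2.0, 0.5),))
        a = sample_metric_groups(spec, seed=11)
        b = sample_metric_groups(spec, seed=11)
        np.testing.assert_array_equal(a[1.0], b[1.0])

    @pytest.mark.parametrize(
        "group",
        [
            (1.0, 2, "normal", 0.0, 1.0),  # n too small
            (1.0, 5, "normal", 0.0, -1.0),  # negative scale
            (1.0, 5, "cauchy", 0.0, 1.0),  # unknown family
        ],
    )
    def test_invalid_spec_rejected(self, group):
        with pytest.raises(ValueError):
            GroupSpec(groups=(group,))
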