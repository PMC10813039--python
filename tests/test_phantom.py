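"""Phantom generator: A-scan structure, determinism, contrast transform."""

import dataclasses

import numpy as np
import pytest

from vitrehaze import (
    ConfigError,
    ContrastStateError,
    InvalidGeometryError,
    PhantomSpec,
    compute_vh,
    contrast_adjust,
    expected_haze_ratio,
    generate_ascan_profile,
    generate_volume,
)
from vitrehaze.ilm import IlmSurface

BOUNDS = np.array([20, 30, 42, 50, 66, 68, 72, 74])
INTENS = np.array([0.75, 0.55, 0.40, 0.20, 1.00, 0.30, 0.95, 0.35])


class TestAscanProfile:
    def test_noiseless_vitreous_at_baseline(self):
        p = generate_ascan_profile(BOUNDS, INTENS, 96, vitreous_baseline=0.05)
        assert np.all(p[:20] == 0.05)

    def test_haze_shifts_vitreous_mean_exactly(self):
        p = generate_ascan_profile(BOUNDS, INTENS, 96, vitreous_baseline=0.05,
                                   haze_level=0.07)
        assert p[:20].mean() == pytest.approx(0.05 + 0.07, rel=1e-15)
        # retina untouched by haze
        assert np.all(p[20:30] == 0.75)

    def test_peaks_at_isos_and_rpe(self):
        p = generate_ascan_profile(BOUNDS, INTENS, 96)
        assert np.all(p[66:68] == 1.0) and np.all(p[72:74] == 0.95)

    def test_speckle_preserves_vitreous_mean(self, rng):
        # Monte-Carlo check of the generator's stated first moment
        h, sigma, n = 0.1, 0.05, 10_000
        draws = np.array([
            generate_ascan_profile(BOUNDS, INTENS, 96, vitreous_baseline=0.05,
                                   haze_level=h, noise_sigma=sigma, rng=rng)[:20]
            for _ in range(n // 20)
        ])
        target = 0.15
        rel_sd = np.sqrt(np.exp(sigma**2) - 1.0)
        se = target * rel_sd / np.sqrt(draws.size)
        assert abs(draws.mean() - target) < 3 * se

    def test_nonincreasing_boundaries_rejected(self):
        bad = BOUNDS.copy()
        bad[3] = bad[2]
        with pytest.raises(InvalidGeometryError):
            generate_ascan_profile(bad, INTENS, 96)

    def test_boundaries_outside_depth_rejected(self):
        with pytest.raises(InvalidGeometryError):
            generate_ascan_profile(BOUNDS, INTENS, 60)


class TestVolume:
    def test_same_seed_bit_identical(self, small_spec):
        v1, t1 = generate_volume(small_spec, 7)
        v2, t2 = generate_volume(small_spec, 7)
        assert np.array_equal(v1.intensities, v2.intensities)
        assert np.array_equal(t1.layer_boundaries, t2.layer_boundaries)

    def test_flat_ilm_step_at_declared_depth(self):
        spec = PhantomSpec(n_bscans=2, n_ascans=8, n_depth=96, noise_sigma=0.0,
                           haze_level=0.0,
                           ilm_depth_map=np.full((2, 8), 24.0))
        vol, truth = generate_volume(spec, 0)
        assert np.all(truth.ilm_depth == 24)
        assert np.all(vol.intensities[..., :24] == spec.vitreous_baseline)
        assert np.all(vol.intensities[..., 24] == 0.75)

    def test_curved_ilm_render_matches_sidecar(self):
        nb, na = 4, 24
        b, a = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
        ilm = 20 + 0.5 * ((b - 1.5) ** 2 + 0.05 * (a - 12) ** 2)
        spec = PhantomSpec(n_bscans=nb, n_ascans=na, n_depth=128, noise_sigma=0.0,
                           haze_level=0.0, ilm_depth_map=ilm)
        vol, truth = generate_volume(spec, 0)
        # first rendered departure from the vitreous baseline per A-scan
        rise = (vol.intensities != spec.vitreous_baseline).argmax(axis=-1)
        assert np.array_equal(rise, truth.ilm_depth)
        assert np.array_equal(truth.ilm_depth, np.rint(ilm).astype(int))

    def test_minimum_depth_enforced(self):
        with pytest.raises(ConfigError):
            PhantomSpec(n_depth=4)

    def test_truth_boundaries_strictly_increasing(self, small_spec):
        _v, truth = generate_volume(small_spec, 3)
        assert np.all(np.diff(truth.layer_boundaries, axis=-1) > 0)


class TestContrastAdjust:
    def test_constant_volume_maps_to_itself(self):
        spec = PhantomSpec(n_bscans=2, n_ascans=4, n_depth=16)
        vol, _ = generate_volume(dataclasses.replace(spec, noise_sigma=0.0), 0)
        vol.intensities[:] = 0.4
        out = contrast_adjust(vol)
        assert np.allclose(out.intensities, 0.4)
        assert out.is_contrast_adjusted

    def test_two_level_ratio_closed_form(self):
        from vitrehaze import RawOctVolume

        arr = np.full((1, 2, 8), 0.1)
        arr[..., 4:] = 0.8
        vol = RawOctVolume(arr, 3.9, 90.0, 500.0)
        out = contrast_adjust(vol, gamma=0.5)
        ratio = out.intensities[..., :4].mean() / out.intensities[..., 4:].mean()
        assert ratio == pytest.approx(np.sqrt(0.125), rel=1e-12)

    def test_double_adjustment_rejected(self, small_spec):
        vol, _ = generate_volume(small_spec, 0)
        adj = contrast_adjust(vol)
        with pytest.raises(ContrastStateError):
            contrast_adjust(adj)

    @pytest.mark.parametrize("seed", range(5))
    def test_adjustment_inflates_subunity_haze(self, seed, small_spec):
        spec = dataclasses.replace(small_spec, haze_level=0.02 * (seed + 1))
        vol, truth = generate_volume(spec, seed)
        surf = IlmSurface(truth.ilm_depth)
        raw = compute_vh(vol, surf)
        adj = compute_vh(contrast_adjust(vol), surf, allow_contrast_adjusted=True)
        assert raw.ratio < 1
        assert adj.ratio > raw.ratio

    def test_expected_ratio_matches_measurement(self):
        spec = PhantomSpec(n_bscans=3, n_ascans=16, n_depth=96, noise_sigma=0.0,
                           haze_level=0.03)
        vol, truth = generate_volume(spec, 0)
        score = compute_vh(vol, IlmSurface(truth.ilm_depth))
        assert score.ratio == pytest.approx(expected_haze_ratio(spec), rel=1e-12)
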