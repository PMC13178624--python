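"""Spectral-map construction and weighted-centroid velocity estimation."""

import numpy as np
import pytest

from sawoce import preprocess, simulate
from sawoce.core_io import PhaseStack, SpectralMap
from sawoce.nsa import (
    NSAConfig,
    SpectrumError,
    auto_roi,
    centroid_velocity,
    complex_slice_stack,
    nsa_profile,
    spectral_map,
)


def _centroid_oracle(S, k_axis, f_axis):
    """Brute-force double-loop spectral centroid (independent of the vectorized path)."""
    num_k = num_f = den = 0.0
    for i in range(S.shape[0]):
        for j in range(S.shape[1]):
            num_k += k_axis[i] * S[i, j]
            num_f += f_axis[j] * S[i, j]
            den += S[i, j]
    return (num_f / den) / (num_k / den)


def _delta_map(k0, f0, value=1.0, nk=8, nf=8):
    S = np.zeros((nk, nf))
    k_axis = np.linspace(100, 5000, nk)
    f_axis = np.linspace(2000, 6000, nf)
    i = int(np.argmin(np.abs(k_axis - k0)))
    j = int(np.argmin(np.abs(f_axis - f0)))
    S[i, j] = value
    k_axis[i], f_axis[j] = k0, f0
    return SpectralMap(S=S, k_axis=np.sort(k_axis), f_axis=np.sort(f_axis),
                       roi=(100, 5000, 2000, 6000))


class TestCentroid:
    def test_delta_spectrum_is_f_over_k(self):
        S = _delta_map(1000.0, 4000.0)
        assert centroid_velocity(S) == pytest.approx(4.0)

    def test_two_equal_masses_average_in_f(self):
        nk, nf = 6, 6
        k_axis = np.linspace(500, 1500, nk)
        f_axis = np.linspace(2000, 6000, nf)
        S = np.zeros((nk, nf))
        S[2, 1] = S[2, 4] = 1.0
        m = SpectralMap(S=S, k_axis=k_axis, f_axis=f_axis, roi=(500, 1500, 2000, 6000))
        expected = ((f_axis[1] + f_axis[4]) / 2) / k_axis[2]
        assert centroid_velocity(m) == pytest.approx(expected)

    def test_matches_double_loop_oracle_on_random_maps(self, rng):
        for _ in range(100):
            nk, nf = rng.integers(2, 9, 2)
            S = rng.random((nk, nf))
            k_axis = np.sort(rng.uniform(100, 6000, nk))
            f_axis = np.sort(rng.uniform(2000, 6000, nf))
            m = SpectralMap(S=S, k_axis=k_axis, f_axis=f_axis, roi=(50, 6500, 1500, 6500))
            expected = _centroid_oracle(S, k_axis, f_axis)
            assert centroid_velocity(m) == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance(self, rng):
        S = rng.random((5, 5))
        k_axis = np.sort(rng.uniform(100, 6000, 5))
        f_axis = np.sort(rng.uniform(2000, 6000, 5))
        m1 = SpectralMap(S=S, k_axis=k_axis, f_axis=f_axis, roi=(50, 6500, 1500, 6500))
        m2 = SpectralMap(S=37.5 * S, k_axis=k_axis, f_axis=f_axis,
                         roi=(50, 6500, 1500, 6500))
        assert centroid_velocity(m1) == pytest.approx(centroid_velocity(m2), rel=1e-12)

    def test_centroid_containment(self, rng):
        """c always lies in [f_min/k_max, f_max/k_min] of the map support."""
        for _ in range(20):
            S = rng.random((4, 4))
            k_axis = np.sort(rng.uniform(100, 6000, 4))
            f_axis = np.sort(rng.uniform(2000, 6000, 4))
            m = SpectralMap(S=S, k_axis=k_axis, f_axis=f_axis, roi=(50, 6500, 1500, 6500))
            c = centroid_velocity(m)
            assert f_axis[0] / k_axis[-1] <= c <= f_axis[-1] / k_axis[0]

    def test_zero_energy_rejected(self):
        m = SpectralMap(S=np.zeros((3, 3)), k_axis=np.array([1e2, 2e2, 3e2]),
                        f_axis=np.array([2e3, 3e3, 4e3]), roi=(50, 400, 1e3, 5e3))
        with pytest.raises(SpectrumError, match="zero total energy"):
            centroid_velocity(m)


class TestAutoROI:
    def test_documented_bracket(self):
        roi_k, roi_f = auto_roi(4000, 1.0, 20.0, band=0.5)
        assert roi_f == (2000.0, 6000.0)
        assert roi_k == (100.0, 6000.0)

    def test_degenerate_band_rejected(self):
        with pytest.raises(ValueError):
            auto_roi(4000, 1.0, 20.0, band=0.0)

    def test_equal_velocities_rejected(self):
        with pytest.raises(ValueError):
            auto_roi(4000, 5.0, 5.0)


class TestSpectralMap:
    def test_plane_wave_lobe_at_analytic_coordinates(self, homog_stack, homog_config):
        """Noiseless travelling wave: dominant bin within one padded bin of (f0/c, f0)."""
        c = homog_config.layers[0][1]
        S = spectral_map(homog_stack, 10)
        i, j = np.unravel_index(S.S.argmax(), S.S.shape)
        dk = S.k_axis[1] - S.k_axis[0]
        df = S.f_axis[1] - S.f_axis[0]
        assert abs(S.k_axis[i] - homog_config.f0 / c) <= dk
        assert abs(S.f_axis[j] - homog_config.f0) <= df

    def test_zero_slice_gives_zero_map(self):
        phase = np.zeros((1, 64, 64))
        stack = PhaseStack(phase=phase, dz=4.7, dx=40.0, dt=1e-5, meta={"f0": 4000.0})
        S = spectral_map(stack, 0, NSAConfig(depth_radius=0))
        assert np.all(S.S == 0)

    def test_edge_depth_truncates_window(self, homog_stack):
        """Estimates exist at the stack edges (window truncated, not padded)."""
        S_edge = spectral_map(homog_stack, 0)
        S_mid = spectral_map(homog_stack, 10)
        assert S_edge.S.shape == S_mid.S.shape
        assert centroid_velocity(S_edge) > 0


class TestProfile:
    @pytest.mark.parametrize("c_true", [3.2, 5.3])
    def test_homogeneous_recovery_within_5pct(self, c_true):
        cfg = simulate.small_config(layers=((64, c_true),), noise_sigma=0.0, seed=21)
        vol = simulate.simulate_volume(cfg)
        flat = preprocess.flatten_volume(vol, preprocess.detect_surface(vol))
        prof = nsa_profile(preprocess.extract_phase_stack(flat, 40))
        assert np.nanmean(prof.v_raw) == pytest.approx(c_true, rel=0.05)

    def test_two_layer_medians_recover_truth(self, layered_config):
        vol = simulate.simulate_volume(layered_config)
        flat = preprocess.flatten_volume(vol, preprocess.detect_surface(vol))
        prof = nsa_profile(preprocess.extract_phase_stack(flat, 40))
        # away from a +/-6-index transition band around the interface at 20
        top = prof.v_raw[:14]
        bottom = prof.v_raw[27:]
        assert np.nanmedian(top) == pytest.approx(5.5, rel=0.05)
        assert np.nanmedian(bottom) == pytest.approx(3.1, rel=0.05)

    def test_monotone_recovery_across_velocities(self):
        """Estimated depth-mean increases strictly with true velocity."""
        means = []
        for c in (2.0, 3.0, 4.0, 5.0, 6.0, 8.0):
            cfg = simulate.small_config(layers=((64, c),), noise_sigma=0.05, seed=31)
            vol = simulate.simulate_volume(cfg)
            flat = preprocess.flatten_volume(vol, preprocess.detect_surface(vol))
            prof = nsa_profile(preprocess.extract_phase_stack(flat, 30))
            means.append(np.nanmean(prof.v_raw))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_noise_robustness_10pct(self):
        """At noise_sigma 0.3 homogeneous recovery stays within 10% (5 seeds)."""
        errs = []
        for seed in range(5):
            cfg = simulate.small_config(layers=((64, 4.0),), noise_sigma=0.3,
                                        seed=100 + seed)
            vol = simulate.simulate_volume(cfg)
            flat = preprocess.flatten_volume(vol, preprocess.detect_surface(vol))
            prof = nsa_profile(preprocess.extract_phase_stack(flat, 30))
            errs.append(abs(np.nanmean(prof.v_raw) / 4.0 - 1))
        assert max(errs) < 0.10

    def test_complex_field_mode_agrees_roughly(self, homog_config):
        """The complex-slice variant recovers the same homogeneous velocity."""
        vol = simulate.simulate_volume(homog_config)
        flat = preprocess.flatten_volume(vol, preprocess.detect_surface(vol))
        stack = complex_slice_stack(flat, 30)
        prof = nsa_profile(stack, NSAConfig(use_complex_field=True))
        assert np.nanmean(prof.v_raw) == pytest.approx(3.2, rel=0.10)
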