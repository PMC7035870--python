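import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import signal as sp_signal
from scipy import stats

import boldsim as bs
from boldsim.datamodel import Volume4D
from boldsim.generation import evaluate_drift, make_drift_basis

from conftest import full_mask


class TestDriftDropoff:
    def test_reference_root(self):
        # frozen oracle: plain bisection of 0.99 = (1 - r^4)/(1 - r^400)
        assert bs.solve_drift_dropoff(300, 1.5, 150) == pytest.approx(
            0.31622776601683755, abs=1e-8
        )

    @pytest.mark.parametrize("L,A,P", [(300, 1.5, 150), (200, 2.0, 100),
                                       (500, 0.8, 150), (120, 3.0, 60)])
    def test_root_satisfies_equation(self, L, A, P):
        r = bs.solve_drift_dropoff(L, A, P)
        assert 0 < r < 1
        assert (1 - r ** (2 * L / P)) / (1 - r ** (2 * L / A)) == pytest.approx(
            0.99, abs=1e-8
        )

    @given(
        L=st.floats(60.0, 1000.0),
        A=st.floats(0.5, 5.0),
        P=st.floats(30.0, 300.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_root_residual_property(self, L, A, P):
        assume(A < P and A / P < 0.9)
        r = bs.solve_drift_dropoff(L, A, P)
        residual = (1 - r ** (2 * L / P)) / (1 - r ** (2 * L / A)) - 0.99
        assert 0 < r < 1
        assert abs(residual) < 1e-8

    def test_equal_periods_have_no_solution(self):
        with pytest.raises(ValueError):
            bs.solve_drift_dropoff(300, 150.0, 150.0)

    def test_ratio_limit_rejected(self):
        with pytest.raises(ValueError, match="0.99"):
            bs.solve_drift_dropoff(300, 149.0, 150.0)


class TestDrift:
    def test_matches_direct_cosine_sum_with_zero_phases(self):
        L, A, P = 60.0, 2.0, 30.0
        n = int(L // A)
        drift = bs.generate_drift(L, A, P, phases=np.zeros(n))
        r = bs.solve_drift_dropoff(L, A, P)
        t = np.arange(n) * A
        i = np.arange(1, n + 1)[:, None]
        direct = (np.cos(i * np.pi * t / L) * r ** (i - 1.0)).sum(axis=0)
        direct = (direct - direct.mean()) / direct.std()
        assert np.allclose(drift, direct)

    @pytest.mark.parametrize("L,A,P", [(300, 1.5, 150), (240, 2.0, 150), (600, 1.0, 100)])
    def test_power_concentrated_below_periodicity(self, L, A, P):
        basis = make_drift_basis(L, A, P, seed=0)
        assert basis.power_fraction_below() >= 0.99

    def test_seeds_change_phases_not_envelope(self):
        b1 = make_drift_basis(300, 1.5, 150, seed=1)
        b2 = make_drift_basis(300, 1.5, 150, seed=2)
        assert not np.allclose(b1.phases, b2.phases)
        assert np.allclose(b1.amplitudes(), b2.amplitudes())
        assert not np.allclose(evaluate_drift(b1), evaluate_drift(b2))


class TestSpatialField:
    def test_standardized(self):
        field = bs.generate_spatial_field((20, 20, 20), (1, 1, 1), 4.0, seed=0)
        assert field.mean() == pytest.approx(0.0, abs=1e-12)
        assert field.var() == pytest.approx(1.0, rel=1e-9)

    def test_small_kernel_limit_is_spatially_white(self):
        field = bs.generate_spatial_field((20, 20, 20), (10, 10, 10), 0.5, seed=1)
        lag1 = np.mean(field[:-1] * field[1:])
        assert abs(lag1) < 0.05

    def test_lag1_autocorrelation_matches_gaussian_kernel(self):
        # circulant embedding: rho(1) = exp(-1/(4 sigma^2)) per axis
        fwhm, vox = 4.0, 2.0
        sigma = fwhm / np.sqrt(8 * np.log(2)) / vox
        expected = np.exp(-1.0 / (4 * sigma**2))
        acs = []
        for s in range(10):
            f = bs.generate_spatial_field((24, 24, 24), (vox, vox, vox), fwhm, seed=s)
            acs.append(np.mean(f[:-1] * f[1:]))
        assert np.mean(acs) == pytest.approx(expected, abs=0.02)


class TestArmaNoise:
    def test_degenerate_recursion_is_white(self):
        field = bs.generate_arma_noise(0.0, 0.0, (6, 6, 4), 400, 2.0, (3, 3, 3), seed=0)
        lag1 = np.mean(field[..., :-1] * field[..., 1:], axis=-1)
        assert abs(lag1.mean()) < 0.03

    def test_lag1_autocorrelation_closed_form(self):
        # ARMA(1,1): rho(1) = (1 + phi om)(phi + om) / (1 + 2 phi om + om^2)
        phi, om = 0.5, 0.2
        expected = (1 + phi * om) * (phi + om) / (1 + 2 * phi * om + om**2)
        assert expected == pytest.approx(0.6209677, abs=1e-6)
        field = bs.generate_arma_noise(phi, om, (4, 4, 1), 2000, 0.5, (3, 3, 3), seed=1)
        lag1 = np.mean(field[..., :-1] * field[..., 1:], axis=-1)
        assert lag1.mean() == pytest.approx(expected, abs=0.05)

    def test_round_trip_through_estimator(self):
        field = bs.generate_arma_noise(0.5, 0.2, (10, 10, 6), 500, 3.0, (3, 3, 3), seed=2)
        vol = Volume4D(field + 100.0)
        phi, om = bs.calc_arma(vol, full_mask((10, 10, 6)), n_voxels=100, seed=0)
        assert phi == pytest.approx(0.5, abs=0.1)
        assert om == pytest.approx(0.2, abs=0.1)

    def test_nonstationary_rejected(self):
        with pytest.raises(ValueError, match="stationarity"):
            bs.generate_arma_noise(1.0, 0.2, (4, 4, 4), 50, 2.0, (3, 3, 3), seed=0)

    def test_variance_stable_across_windows(self):
        # stationarity: per-window variance shows no drift for |phi| < 1
        field = bs.generate_arma_noise(0.8, 0.1, (6, 6, 4), 500, 2.0, (3, 3, 3), seed=3)
        windows = np.array_split(np.arange(500), 10)
        var_per_window = [field[..., w].var() for w in windows]
        assert max(var_per_window) / min(var_per_window) < 2.0


class TestPhysiologicalNoise:
    def test_spectral_peaks_at_cardiac_and_respiratory_rates(self):
        wave = bs.generate_physiological_noise(4000, 0.25, seed=0)
        freqs, power = sp_signal.periodogram(wave, fs=4.0)
        top2 = freqs[np.argsort(power)[-2:]]
        assert sorted(np.round(top2, 3).tolist()) == [0.2, 1.17]

    def test_cardiac_component_aliases_at_long_tr(self):
        # fs = 1/1.5 Hz; 1.17 Hz folds to |1.17 - 2*fs| = 0.1633 Hz
        wave = bs.generate_physiological_noise(2000, 1.5, seed=1)
        freqs, power = sp_signal.periodogram(wave, fs=1.0 / 1.5)
        top2 = sorted(freqs[np.argsort(power)[-2:]])
        assert top2[0] == pytest.approx(abs(1.17 - 2 / 1.5), abs=0.002)
        assert top2[1] == pytest.approx(0.2, abs=0.002)

    def test_zero_phases_give_deterministic_waveform(self):
        T, A = 50, 0.25
        wave = bs.generate_physiological_noise(T, A, phases=(0.0, 0.0))
        t = np.arange(T) * A
        direct = np.sin(2 * np.pi * 1.17 * t) + np.sin(2 * np.pi * 0.2 * t)
        direct = (direct - direct.mean()) / direct.std()
        assert np.allclose(wave, direct)


class TestTaskNoise:
    def test_no_events_returns_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="no events"):
            out = bs.generate_task_noise(np.zeros(50), seed=0)
        assert np.array_equal(out, np.zeros(50))

    def test_all_events_gaussian_is_standardized_white(self):
        out = bs.generate_task_noise(np.ones(5000), dist="gaussian", seed=1)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, rel=1e-9)
        assert abs(np.corrcoef(out[:-1], out[1:])[0, 1]) < 0.05

    def test_rician_with_large_location_approaches_gaussian(self):
        out = bs.generate_task_noise(
            np.ones(10_000), dist="rician", sigma=1.0, rician_nu=100.0, seed=2
        )
        d, _ = stats.kstest(out, "norm")
        assert d < 0.05

    def test_noise_only_at_event_volumes(self):
        stim = np.zeros(100)
        stim[10:20] = 1.0
        out = bs.generate_task_noise(stim, seed=3)
        assert np.all(out[stim == 0] == 0.0)
        assert np.any(out[stim > 0] != 0.0)


class TestMixing:
    def _components(self, mask, T=200, seed=0):
        rng = np.random.default_rng(seed)
        dims = mask.data.shape
        v_arma = rng.standard_normal(dims + (T,))
        v_arma = (v_arma - v_arma.mean(-1, keepdims=True)) / v_arma.std(-1, keepdims=True)
        v_physio = rng.standard_normal(T)
        v_physio = (v_physio - v_physio.mean()) / v_physio.std()
        v_task = rng.standard_normal(T)
        v_task = (v_task - v_task.mean()) / v_task.std()
        v_drift = np.zeros(T)
        return bs.TemporalNoiseComponents(
            v_arma=v_arma, v_physio=v_physio, v_task=v_task, v_drift=v_drift, W=12.0
        )

    def test_degenerate_weights_reproduce_arma_exactly(self, small_mask):
        comps = self._components(small_mask)
        params = bs.NoiseParameters(w_arma=1.0, w_physio=0.0, w_task=0.0, w_drift=0.0)
        out = bs.mix_temporal_noise(comps, params, small_mask)
        assert np.allclose(out[small_mask.data], comps.W * comps.v_arma[small_mask.data])
        assert np.all(out[~small_mask.data] == 0.0)

    def test_variance_of_weighted_independent_sum(self, small_mask):
        comps = self._components(small_mask, seed=4)
        params = bs.NoiseParameters(w_arma=0.5, w_physio=0.25, w_task=0.25, w_drift=0.0)
        raw = bs.mix_temporal_noise(comps, params, small_mask, restandardize=False)
        expected = comps.W * np.sqrt(0.5**2 + 0.25**2 + 0.25**2)
        assert raw[small_mask.data].std(-1).mean() == pytest.approx(expected, rel=0.05)
        final = bs.mix_temporal_noise(comps, params, small_mask, restandardize=True)
        assert final[small_mask.data].std(-1).mean() == pytest.approx(comps.W, rel=0.05)

    def test_weight_sum_violation_rejected(self, small_mask):
        comps = self._components(small_mask)
        params = bs.NoiseParameters(w_arma=0.5, w_physio=0.25, w_task=0.25)
        object.__setattr__(params, "w_task", 0.15)  # bypass constructor check
        with pytest.raises(ValueError, match="sum to 1"):
            bs.mix_temporal_noise(comps, params, small_mask)


class TestSystemNoise:
    def test_vanishing_noise_at_huge_snr(self, small_template, small_mask):
        out = bs.generate_system_noise(small_template, small_mask, 1e9, 70.0, T=4, seed=0)
        brain_mean = small_template.data[small_mask.data].mean()
        assert out.std() < 1e-3 * brain_mean

    def test_snr_round_trip(self):
        template = bs.synthetic_template(dims=(24, 24, 16), brain_intensity=1000.0,
                                         background_scale=0.0, seed=5)
        mask = bs.compute_mask(template)
        out = bs.generate_system_noise(template, mask, 50.0, 70.0, T=4, seed=1)
        mid = out[..., 2] + template.data[..., None][..., 0]
        assert mid[~mask.data].std() == pytest.approx(1000.0 / 50.0, rel=0.05)
        vol = Volume4D(template.data[..., None] + out)
        assert bs.calc_snr(vol, mask) == pytest.approx(50.0, rel=0.05)

    def test_seeds_differ_but_statistics_agree(self, small_template, small_mask):
        a = bs.generate_system_noise(small_template, small_mask, 40.0, 70.0, T=4, seed=1)
        b = bs.generate_system_noise(small_template, small_mask, 40.0, 70.0, T=4, seed=2)
        assert not np.allclose(a, b)
        assert a.std() == pytest.approx(b.std(), rel=0.1)


class TestGenerateNoise:
    def test_fitted_simulation_matches_targets(self, desk_mask, fitted_scan):
        vol, params = fitted_scan
        assert bs.calc_snr(vol, desk_mask) == pytest.approx(params.snr, rel=0.05)
        assert bs.calc_sfnr(vol, desk_mask) == pytest.approx(params.sfnr, rel=0.05)

    def test_unfitted_assembly_decomposes(self, small_template, small_mask):
        params = bs.NoiseParameters(snr=1e9, sfnr=70.0, w_arma=1.0, w_physio=0.0,
                                    w_task=0.0, w_drift=0.0)
        vol = bs.generate_noise(small_template, small_mask, params, T=80, tr=1.5,
                                fit=False, seed=6)
        resid = vol.data - small_template.data[..., None]
        W = small_template.data[small_mask.data].mean() / 70.0
        # brain voxels carry temporal noise of std W; non-brain only static noise
        assert resid[small_mask.data].std(-1).mean() == pytest.approx(W, rel=0.02)
        assert resid[~small_mask.data].std(-1).max() < 1e-6 * W

    def test_same_seed_is_bit_identical(self, small_template, small_mask):
        params = bs.NoiseParameters()
        kw = dict(T=40, tr=1.5, fit=False, seed=9)
        v1 = bs.generate_noise(small_template, small_mask, params, **kw)
        v2 = bs.generate_noise(small_template, small_mask, params, **kw)
        assert np.array_equal(v1.data, v2.data)

    def test_task_weight_without_stimulus_rejected(self, small_template, small_mask):
        params = bs.NoiseParameters(w_arma=0.8, w_physio=0.1, w_task=0.1)
        with pytest.raises(ValueError, match="stim"):
            bs.generate_noise(small_template, small_mask, params, T=40, seed=0)
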