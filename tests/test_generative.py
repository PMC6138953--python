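"""Forward model: priors, transfer functions, predicted CSD, simulator."""

import numpy as np
import pytest
from scipy import signal

from dynspdcm.data import ConnectivityMatrix
from dynspdcm.errors import UnstableSystemError
from dynspdcm.generative import (
    ALPHA_BASE,
    DCMParams,
    HemodynamicParams,
    NoiseHyperparams,
    ParameterLayout,
    default_priors,
    predicted_csd,
    simulate_bold,
    transfer_function,
)
from dynspdcm.simulation import A0_BENCHMARK

TR = 0.72
FREQS = np.linspace(0.01, 0.69, 32)


def _benchmark_theta():
    pm, pc, layout = default_priors(4)
    theta = pm.copy()
    theta[layout.a_slice] = (
        ConnectivityMatrix(A0_BENCHMARK, "rate").to_log_scaled().values.ravel()
    )
    return theta, pm, pc, layout


class TestDefaultPriors:
    def test_dimensions_and_psd(self):
        pm, pc, layout = default_priors(4)
        # 16 coupling + 6 shared hemodynamic + 4 noise hyperparameters
        assert layout.n_params == 26
        assert pm.shape == (26,) and pc.shape == (26, 26)
        assert np.linalg.eigvalsh(0.5 * (pc + pc.T)).min() > 0
        # exponents centred at 1: pink innovations at the prior mean
        assert pm[layout.noise_slice][1] == 1.0
        assert pm[layout.noise_slice][3] == 1.0

    def test_per_region_hemodynamics_layout(self):
        _, _, layout = default_priors(3, shared_hemodynamics=False)
        assert layout.n_params == 9 + 18 + 4

    def test_requires_two_regions(self):
        with pytest.raises(ValueError):
            default_priors(1)


class TestTransferFunction:
    def test_scalar_resolvent_oracle(self):
        lay = ParameterLayout(1)
        th = np.zeros(lay.n_params)
        th[0] = np.log(0.3 / 0.5)  # effective self-connection -0.3 Hz
        K = transfer_function(th, FREQS, lay, include_hemodynamics=False)
        closed = 1.0 / (2j * np.pi * FREQS + 0.3)
        np.testing.assert_allclose(K.values[:, 0, 0], closed, atol=1e-10)

    def test_low_pass_beyond_point_two(self):
        pm, _, layout = default_priors(2)
        K = transfer_function(pm, np.linspace(0.01, 0.6, 60), layout)
        mag = np.abs(K.values[:, 0, 0])
        tail = mag[np.linspace(0.01, 0.6, 60) > 0.2]
        assert np.all(np.diff(tail) < 0)

    def test_decoupled_system_block_diagonal(self):
        pm, _, layout = default_priors(3)
        K = transfer_function(pm, FREQS, layout)  # prior mean: A off-diag = 0
        off = K.values[:, ~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 1e-14

    def test_unstable_raises(self):
        pm, _, layout = default_priors(2)
        th = pm.copy()
        th[1] = 2.0  # strong positive coupling
        th[2] = 2.0
        with pytest.raises(UnstableSystemError):
            transfer_function(th, FREQS, layout)

    def test_matches_impulse_response_fourier(self):
        # FD/quadrature oracle: Fourier transform of the linearised
        # impulse response on a 2-region system
        pm, _, layout = default_priors(2)
        th = pm.copy()
        th[1] = 0.2  # coupling 0 <- 1
        K = transfer_function(th, np.array([0.01, 0.03]), layout)
        from dynspdcm.generative import _effective_a, _hemo_jacobian, _hemo_output

        A = _effective_a(th[layout.a_slice].reshape(2, 2))
        hemo = HemodynamicParams()
        Jh = _hemo_jacobian(hemo.kappa, hemo.gamma, hemo.transit, hemo.alpha, hemo.e0)
        c = _hemo_output(hemo.e0, hemo.epsilon)
        # full linear system: x (2) + per-region balloon states (2x4)
        n = 2
        M = np.zeros((n + 4 * n, n + 4 * n))
        M[:n, :n] = A
        for r in range(n):
            sl = slice(n + 4 * r, n + 4 * r + 4)
            M[sl, sl] = Jh
            M[n + 4 * r, r] = 1.0  # x drives s
        dt, T = 0.05, 600.0
        t = np.arange(0, T, dt)
        out = np.zeros((t.size, n, n))
        for j in range(n):
            x0 = np.zeros(n + 4 * n)
            x0[j] = 1.0
            from scipy.linalg import expm

            P = expm(M * dt)
            state = x0
            for k in range(t.size):
                for r in range(n):
                    out[k, r, j] = c @ state[n + 4 * r : n + 4 * r + 4]
                state = P @ state
        for fi, f in enumerate([0.01, 0.03]):
            Kq = (out * np.exp(-2j * np.pi * f * t)[:, None, None]).sum(axis=0) * dt
            np.testing.assert_allclose(Kq, K.values[fi], rtol=0.01, atol=1e-3)


class TestPredictedCsd:
    def test_hermitian_nonnegative_over_prior_draws(self):
        pm, pc, layout = default_priors(3)
        rng = np.random.default_rng(0)
        done = 0
        while done < 8:
            th = rng.multivariate_normal(pm, pc)
            try:
                S = predicted_csd(th, FREQS, layout)
            except UnstableSystemError:
                continue
            assert S.is_hermitian()
            assert S.auto_spectra().min() >= -1e-12
            done += 1

    def test_homogeneity_in_alpha_v(self):
        theta, *_, layout = _benchmark_theta()
        th2 = theta.copy()
        th2[layout.noise_slice.start] += np.log(2.0)
        S1 = predicted_csd(theta, FREQS, layout).values
        S2 = predicted_csd(th2, FREQS, layout).values
        # off-diagonals carry no observation noise: exact doubling
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(S2[:, off], 2 * S1[:, off], rtol=1e-12)

    def test_matches_long_nonlinear_simulation(self):
        # linearisation oracle: averaged cross-periodogram of a long
        # nonlinear simulation; tolerance reflects the Welch sampling
        # floor (~7% at this segmentation) plus linearisation bias
        theta, *_, layout = _benchmark_theta()
        A0 = ConnectivityMatrix(A0_BENCHMARK, "rate")
        ts = simulate_bold([A0] * 250, HemodynamicParams(), NoiseHyperparams(),
                           200, TR, seed=3)
        freqs = np.linspace(0.02, 0.1, 20)
        S_pred = predicted_csd(theta, freqs, layout).values
        y = ts.data - ts.data.mean(0)
        S_emp = np.zeros((freqs.size, 4, 4), complex)
        for i in range(4):
            for j in range(4):
                f_w, P = signal.csd(y[:, i], y[:, j], fs=1 / TR, nperseg=512)
                Pc = np.conj(P) / 2  # scipy E[X_i* X_j], one- to two-sided
                S_emp[:, i, j] = np.interp(freqs, f_w, Pc.real) + 1j * np.interp(
                    freqs, f_w, Pc.imag
                )
        rel = np.linalg.norm(S_pred - S_emp) / np.linalg.norm(S_emp)
        assert rel < 0.15


class TestSimulateBold:
    def test_deterministic_given_seed(self):
        A0 = ConnectivityMatrix(A0_BENCHMARK, "rate")
        a = simulate_bold([A0] * 2, HemodynamicParams(), NoiseHyperparams(), 100, TR, seed=4)
        b = simulate_bold([A0] * 2, HemodynamicParams(), NoiseHyperparams(), 100, TR, seed=4)
        np.testing.assert_array_equal(a.data, b.data)

    def test_noise_free_fixed_point(self):
        A0 = ConnectivityMatrix(A0_BENCHMARK, "rate")
        ts = simulate_bold([A0] * 2, HemodynamicParams(),
                           NoiseHyperparams(0.0, 1.0, 0.0, 1.0), 80, TR, seed=0)
        np.testing.assert_allclose(ts.data, 0.0, atol=1e-9)

    def test_benchmark_shape(self):
        A0 = ConnectivityMatrix(A0_BENCHMARK, "rate")
        ts = simulate_bold([A0] * 15, HemodynamicParams(), NoiseHyperparams(), 200, TR, seed=0)
        assert ts.data.shape == (3000, 4)
        assert np.all(np.isfinite(ts.data))

    def test_unstable_schedule_rejected(self):
        bad = np.array([[0.1, 0.0], [0.0, -0.5]])
        with pytest.raises(UnstableSystemError):
            simulate_bold([bad], HemodynamicParams(), NoiseHyperparams(), 10, TR, seed=0)

    def test_seed_stability_of_long_run_covariance(self):
        A0 = ConnectivityMatrix(A0_BENCHMARK, "rate")
        covs = []
        for seed in (0, 1):
            ts = simulate_bold([A0] * 75, HemodynamicParams(), NoiseHyperparams(),
                               200, TR, seed=seed)
            y = ts.data - ts.data.mean(0)
            C = y.T @ y / y.shape[0]
            assert np.linalg.eigvalsh(C).min() > 0
            covs.append(C)
        # 15000-scan runs: sampling deviation scales as 1/sqrt(n)
        dev = np.linalg.norm(covs[0] - covs[1]) / np.linalg.norm(covs[0])
        assert dev < 0.20


def test_dcm_params_vector_roundtrip():
    layout = ParameterLayout(3)
    rng = np.random.default_rng(0)
    theta = 0.1 * rng.standard_normal(layout.n_params)
    theta[layout.noise_slice][[1, 3]] += 1.0
    params = DCMParams.from_vector(theta, layout)
    np.testing.assert_allclose(params.to_vector(layout), theta, atol=1e-12)
    assert params.noise.alpha_v > 0
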