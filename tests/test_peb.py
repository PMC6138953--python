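"""Hierarchical PEB: GLM oracles, model reduction, recursion, iteration."""

import numpy as np
import pytest

from dynspdcm.bases import dct_column, make_dct_basis
from dynspdcm.errors import SingularDesignError
from dynspdcm.generative import default_priors, predicted_csd
from dynspdcm.peb import (
    PEB,
    PEBConfig,
    compare_basis_subsets,
    fit_peb,
    iterative_peb_fit,
    peb_of_peb,
    reduce_model,
)
from dynspdcm.spectral import CrossSpectralDensity

FLAT = PEBConfig(beta_prior_variance=1e8)


class TestFitPebOracles:
    def test_equal_covariances_give_arithmetic_mean(self):
        rng = np.random.default_rng(0)
        mu = rng.standard_normal(6)
        means = [mu + 0.1 * rng.standard_normal(6) for _ in range(12)]
        pairs = [(m, 0.01 * np.eye(6)) for m in means]
        res = fit_peb(pairs, make_dct_basis(12, 1), config=FLAT)
        b0 = res.beta[0] * res.design[0, 0]
        np.testing.assert_allclose(b0, np.mean(means, axis=0), atol=1e-8)

    def test_unequal_covariances_give_precision_weighted_mean(self):
        rng = np.random.default_rng(1)
        means, covs = [], []
        for _ in range(8):
            means.append(rng.standard_normal(4))
            d = rng.uniform(0.01, 0.5, size=4)
            covs.append(np.diag(d))
        # pin the between-unit variance at (numerically) zero so the
        # closed-form GLS oracle uses the stated covariances alone
        cfg = PEBConfig(beta_prior_variance=1e8, fixed_gamma=40.0)
        res = fit_peb(list(zip(means, covs)), make_dct_basis(8, 1), config=cfg)
        b0 = res.beta[0] * res.design[0, 0]
        W = [np.linalg.inv(c) for c in covs]
        oracle = np.linalg.solve(sum(W), sum(w @ m for w, m in zip(W, means)))
        np.testing.assert_allclose(b0, oracle, atol=1e-8)

    def test_single_unit_identity(self):
        rng = np.random.default_rng(2)
        m = rng.standard_normal(5)
        S = np.diag(rng.uniform(0.05, 0.2, 5))
        cfg = PEBConfig(beta_prior_variance=1e8, fixed_gamma=40.0)
        res = fit_peb([(m, S)], np.ones((1, 1)), config=cfg)
        np.testing.assert_allclose(res.beta[0], m, atol=1e-7)
        assert np.all(np.diag(res.beta_covariance) >= np.diag(S) - 1e-8)

    def test_singular_design_rejected(self):
        pairs = [(np.zeros(3), np.eye(3))] * 4
        X = np.ones((4, 2))  # duplicated constant column
        with pytest.raises(SingularDesignError):
            fit_peb(pairs, X)


class TestModelReduction:
    def _toy(self, effect=0.0, seed=0, U=12, P=3):
        rng = np.random.default_rng(seed)
        mu = rng.standard_normal(P)
        amp = effect * rng.standard_normal(P)
        cos = dct_column(U, 1)
        pairs = [
            (mu + cos[i] * amp + 0.05 * rng.standard_normal(P), 0.0025 * np.eye(P))
            for i in range(U)
        ]
        return fit_peb(pairs, make_dct_basis(U, 2), config=PEBConfig(fixed_gamma=2.0))

    def test_full_mask_is_identity(self):
        full = self._toy(effect=0.5)
        assert reduce_model(full, [True, True]).delta_free_energy == 0.0

    def test_null_data_prefer_reduced_model(self):
        wins = 0
        for seed in range(5):
            full = self._toy(effect=0.0, seed=seed)
            ev = reduce_model(full, [True, False])
            wins += ev.delta_free_energy > 0
        assert wins >= 4

    def test_reduction_matches_explicit_refit(self):
        # Savage-Dickey evidence vs a from-scratch refit under the
        # reduced design (same fixed between-unit variance)
        rng = np.random.default_rng(5)
        P, U = 2, 10
        mu = rng.standard_normal(P)
        cos = dct_column(U, 1)
        pairs = [
            (mu + 0.3 * cos[i] + 0.05 * rng.standard_normal(P), 0.01 * np.eye(P))
            for i in range(U)
        ]
        cfg = PEBConfig(beta_prior_variance=0.1, fixed_gamma=1.5)
        full = fit_peb(pairs, make_dct_basis(U, 2), config=cfg)
        red = fit_peb(pairs, make_dct_basis(U, 1), config=cfg)
        dF_bmr = reduce_model(full, [True, False]).delta_free_energy
        dF_refit = red.free_energy - full.free_energy
        assert dF_bmr == pytest.approx(dF_refit, abs=0.5)

    def test_constant_column_protected(self):
        full = self._toy(effect=0.2)
        with pytest.raises(ValueError):
            reduce_model(full, [False, True])


class TestCompareSubsets:
    def test_six_columns_give_32_models(self):
        rng = np.random.default_rng(6)
        pairs = [(rng.standard_normal(3), 0.01 * np.eye(3)) for _ in range(12)]
        full = fit_peb(pairs, make_dct_basis(12, 6))
        models = compare_basis_subsets(full)
        assert len(models) == 32
        assert sum(m.posterior_probability for m in models) == pytest.approx(1.0, abs=1e-10)
        assert len({m.model_id for m in models}) == 32

    def test_degenerate_single_model(self):
        rng = np.random.default_rng(7)
        pairs = [(rng.standard_normal(3), 0.01 * np.eye(3)) for _ in range(6)]
        full = fit_peb(pairs, make_dct_basis(6, 1))
        models = compare_basis_subsets(full)
        assert len(models) == 1 and models[0].posterior_probability == 1.0


class TestPebOfPeb:
    def _lower(self, beta, seed, scale=0.01):
        rng = np.random.default_rng(seed)
        pairs = [(beta + scale * rng.standard_normal(beta.size), 0.01 * np.eye(beta.size))
                 for _ in range(6)]
        return fit_peb(pairs, make_dct_basis(6, 1), config=PEBConfig(fixed_gamma=2.0))

    def test_replication_shrinks_covariance(self):
        beta = np.array([0.3, -0.2, 0.1])
        lows = [self._lower(beta, seed=s, scale=0.0) for s in range(4)]
        res = peb_of_peb(lows, np.ones((4, 1)), config=FLAT)
        np.testing.assert_allclose(res.beta[0], lows[0].beta.ravel(), atol=1e-6)
        assert np.all(np.diag(res.beta_covariance) <= np.diag(lows[0].beta_covariance) + 1e-10)

    def test_single_lower_level_is_identity(self):
        # degenerate hierarchy: one session feeding the group level
        beta = np.array([0.3, -0.1])
        low = self._lower(beta, seed=11, scale=0.02)
        cfg = PEBConfig(beta_prior_variance=1e8, fixed_gamma=40.0)
        grp = peb_of_peb([low], np.ones((1, 1)), config=cfg)
        np.testing.assert_allclose(grp.beta[0], low.beta.ravel(), atol=1e-6)

    def test_order_invariance_under_ones_design(self):
        beta = np.array([0.5, 0.0])
        lows = [self._lower(beta, seed=s, scale=0.05) for s in range(4)]
        a = peb_of_peb(lows, np.ones((4, 1)), config=FLAT)
        b = peb_of_peb(lows[::-1], np.ones((4, 1)), config=FLAT)
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-10)

    def test_between_level_variance_recovery(self):
        rng = np.random.default_rng(9)
        tau2 = 0.04
        P, U = 3, 30
        mu = np.array([0.4, -0.1, 0.2])
        pairs = [
            (mu + np.sqrt(tau2) * rng.standard_normal(P), 0.001 * np.eye(P))
            for _ in range(U)
        ]
        res = fit_peb(pairs, np.ones((U, 1)), Q=np.ones(P), config=FLAT)
        est = res.between_var[0]
        assert est == pytest.approx(tau2, rel=0.5)


class TestIterativePeb:
    def _window_csds(self, n_windows, seed=0):
        pm, pc, layout = default_priors(2)
        rng = np.random.default_rng(seed)
        theta = pm.copy()
        theta[1], theta[2] = 0.25, -0.2
        freqs = np.linspace(0.01, 0.3, 24)
        csds = []
        for _ in range(n_windows):
            S = predicted_csd(theta, freqs, layout).values
            scale = np.abs(np.einsum("fii->fi", S))
            E = 0.05 * np.sqrt(scale[:, :, None] * scale[:, None, :]) * (
                rng.standard_normal(S.shape) + 1j * rng.standard_normal(S.shape)
            )
            E = 0.5 * (E + np.conj(np.transpose(E, (0, 2, 1))))
            csds.append(CrossSpectralDensity(freqs, S + E, kind="observed"))
        return csds, pm, pc, layout, theta

    def test_single_window_reduces_to_plain_fit(self):
        csds, pm, pc, layout, theta = self._window_csds(1)
        cfg = PEBConfig(beta_prior_variance=1e8, fixed_gamma=40.0)
        peb, fits = iterative_peb_fit(
            csds, make_dct_basis(1, 1), pm, pc, layout, peb_config=cfg
        )
        assert len(fits) == 1
        np.testing.assert_allclose(
            peb.beta[0] * peb.design[0, 0], fits[0].a_posterior()[0], atol=0.05
        )

    def test_cycle_trace_non_decreasing(self):
        csds, pm, pc, layout, theta = self._window_csds(4, seed=3)
        peb, fits = iterative_peb_fit(csds, make_dct_basis(4, 2), pm, pc, layout)
        trace = peb.cycle_trace
        assert len(trace) >= 1
        assert np.all(np.diff(trace) >= 0)

    def test_recovers_common_coupling(self):
        csds, pm, pc, layout, theta = self._window_csds(4, seed=4)
        peb, fits = iterative_peb_fit(csds, make_dct_basis(4, 1), pm, pc, layout)
        b0 = peb.beta[0] * peb.design[0, 0]
        np.testing.assert_allclose(b0[[1, 2]], theta[[1, 2]], atol=0.08)
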