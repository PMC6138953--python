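"""Hierarchical parametric empirical Bayes over DCM parameters.

The second level is a linear model on first-level posterior moments:
window (or session, or subject) posterior means m_i are treated as data
with known within-unit covariance S_i,

    m_i ~ N(X_i beta, S_i + Sigma2),    Sigma2 = exp(-gamma) * Q,

with a single log-precision gamma scaling one between-unit covariance
component Q (the prior covariance of the included parameter block).
For fixed gamma the model is linear-Gaussian, so the posterior over beta
and the marginal likelihood are available in closed form; gamma is
optimised by bounded scalar search under a Gaussian hyperprior.

Bayesian model reduction over design columns uses the Savage-Dickey
identity (exact for nested point-zero priors with a factorised prior):
the evidence change for switching a column's prior to a point mass at
zero is ln p(beta_c = 0 | data) - ln p(beta_c = 0).

Applying the same machinery to (beta, beta covariance) pairs from a
lower PEB level gives "PEB of PEB" — across sessions and subjects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .bases import TemporalBasisSet
from .errors import SingularDesignError
from .inversion import InversionConfig, SpDCMResults, SpectralDCM
from .spectral import CrossSpectralDensity

_LN2PI = float(np.log(2.0 * np.pi))


@dataclass
class PEBConfig:
    """Settings for one PEB level.

    beta_prior_variance overrides the default informative prior on
    second-level effects (default: scaled from the component covariance
    Q so that the implied per-unit effect has the first-level prior
    scale); pass a large value for an effectively flat prior.
    """

    beta_prior_variance: float | None = None
    gamma_hyper_mean: float = 0.0
    gamma_hyper_var: float = 1.0
    gamma_bounds: tuple[float, float] = (-8.0, 8.0)
    fixed_gamma: float | None = None
    max_cycles: int = 8
    cycle_tol: float = 0.25
    allow_drop_constant: bool = False


@dataclass
class ReducedModelEvidence:
    """Evidence of one nested model (subset of design columns)."""

    mask: np.ndarray
    delta_free_energy: float
    posterior_probability: float | None = None

    @property
    def model_id(self) -> int:
        return int(sum(int(b) << i for i, b in enumerate(self.mask)))


@dataclass
class PEBResults:
    """Second-level expectations, their covariance, and the evidence proxy.

    beta is (K, P): one row per design column, each a vector over the
    modelled parameter block.  beta_covariance is the full (K*P, K*P)
    posterior covariance, ordered by design column.
    """

    beta: np.ndarray
    beta_covariance: np.ndarray
    design: np.ndarray
    gamma: float
    between_var: np.ndarray
    free_energy: float
    beta_prior_var: np.ndarray
    level: str = "windows"
    param_names: list[str] | None = None
    config: PEBConfig = field(default_factory=PEBConfig)
    moments: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def K(self) -> int:
        return self.design.shape[1]

    @property
    def n_params(self) -> int:
        return self.beta.shape[1]

    def predicted_first_level(self) -> np.ndarray:
        """Second-level prediction X beta for every unit, shape (U, P)."""
        return self.design @ self.beta

    def baseline_matrix(self, n_regions: int | None = None) -> np.ndarray:
        """Baseline component A0 in per-unit units (constant column effect)."""
        b0 = self.beta[0] * self.design[0, 0]
        if n_regions is None:
            n_regions = int(round(np.sqrt(b0.size)))
        return b0.reshape(n_regions, n_regions)

    def component_matrix(self, k: int, n_regions: int | None = None) -> np.ndarray:
        """Effect-size matrix for design column k (in beta units)."""
        b = self.beta[k]
        if n_regions is None:
            n_regions = int(round(np.sqrt(b.size)))
        return b.reshape(n_regions, n_regions)

    def beta_credible_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_covariance)).reshape(self.beta.shape)

    # -- model reduction ---------------------------------------------------
    def reduce(self, mask) -> ReducedModelEvidence:
        return reduce_model(self, mask)

    def compare_subsets(self, always_keep_first: bool = True) -> list[ReducedModelEvidence]:
        return compare_basis_subsets(self, always_keep_first)

    def summary(self) -> str:
        sd = self.beta_credible_sd()
        lines = [
            f"PEB ({self.level}); units: {self.design.shape[0]}, design columns: {self.K}",
            f"  free energy: {self.free_energy:.2f} nats",
            f"  between-unit log-precision gamma: {self.gamma:.3f}"
            f"  (variance scale {np.exp(-self.gamma):.4f})",
        ]
        for k in range(self.K):
            top = np.argsort(-np.abs(self.beta[k]))[:4]
            desc = ", ".join(
                f"{(self.param_names or [str(i) for i in range(self.n_params)])[i]}"
                f"={self.beta[k, i]:.3f}±{sd[k, i]:.3f}"
                for i in top
            )
            lines.append(f"  column {k}: {desc}")
        return "\n".join(lines)


class _Unit:
    """Per-unit first-level summary in the form the GLM consumes.

    Two modes:

    * ``raw`` — a (mean, covariance) pair treated directly as noisy
      pseudo-data: m ~ N(X beta, S + Sigma2).
    * ``bmr`` — a Gaussian posterior *with its own prior*: the unit's
      contribution is the evidence change for swapping that prior's
      block to N(X beta, Sigma2) (Bayesian model reduction), carried in
      precision space so weakly identified directions never have to be
      deconvolved.  The two modes coincide when the data evidence
      (posterior minus prior precision) is full rank.
    """

    def __init__(self, mean, cov, prior_mean=None, prior_cov=None):
        self.m = np.asarray(mean, float)
        S = np.asarray(cov, float)
        if S.ndim == 1:
            S = np.diag(S)
        self.S = S
        if prior_mean is None:
            self.mode = "raw"
            return
        self.mode = "bmr"
        p0m = np.asarray(prior_mean, float)
        P0 = np.asarray(prior_cov, float)
        if P0.ndim == 1:
            P0 = np.diag(P0)
        Pq = np.linalg.inv(S)
        P0inv = np.linalg.inv(P0)
        lam = Pq - P0inv
        lam = 0.5 * (lam + lam.T)
        w, V = np.linalg.eigh(lam)
        self.lam = (V * np.clip(w, 0.0, None)) @ V.T  # data-only precision
        self.c = Pq @ self.m - P0inv @ p0m  # data-only information vector
        s1, ldq = np.linalg.slogdet(Pq)
        s2, ld0 = np.linalg.slogdet(P0inv)
        self.k_const = 0.5 * (ldq - ld0) - 0.5 * (
            float(self.m @ Pq @ self.m) - float(p0m @ P0inv @ p0m)
        )


def _extract_units(first_level, block: str = "a", mode: str = "raw") -> list[_Unit]:
    units = []
    for item in first_level:
        if isinstance(item, SpDCMResults):
            if block == "a":
                sl = item.layout.a_slice
                m, S = item.a_posterior()
                pmu = item.prior_mean[sl]
                pc = item.prior_covariance[sl, sl]
            else:
                m, S = item.posterior_mean, item.posterior_covariance
                pmu, pc = item.prior_mean, item.prior_covariance
            units.append(_Unit(m, S, pmu, pc) if mode == "bmr" else _Unit(m, S))
        elif isinstance(item, PEBResults):
            if mode == "bmr":
                units.append(
                    _Unit(
                        item.beta.ravel(),
                        item.beta_covariance,
                        np.zeros(item.beta.size),
                        np.diag(item.beta_prior_var),
                    )
                )
            else:
                units.append(_Unit(item.beta.ravel(), item.beta_covariance))
        else:
            m, S = item
            units.append(_Unit(m, S))
    return units


class PEB:
    """PEB model over first-level posterior moments.

    Parameters
    ----------
    first_level : list of SpDCMResults or (mean, cov) pairs
    design : TemporalBasisSet or ndarray (units x K)
    Q : ndarray (P,), optional
        Diagonal of the between-unit covariance component; defaults to
        1/64 per parameter (the first-level prior scale of coupling
        parameters).
    """

    def __init__(
        self,
        first_level,
        design,
        Q: np.ndarray | None = None,
        config: PEBConfig | None = None,
        level: str = "windows",
        block: str = "a",
        mode: str = "raw",
        param_names: list[str] | None = None,
    ):
        self.units = _extract_units(first_level, block, mode)
        self.m = np.asarray([u.m for u in self.units])
        self.S = np.asarray([u.S for u in self.units])
        X = design.matrix if isinstance(design, TemporalBasisSet) else np.asarray(design, float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != self.m.shape[0]:
            raise ValueError("design rows must match number of first-level units")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise SingularDesignError("singular design")
        self.X = X
        self.U, self.P = self.m.shape
        self.K = X.shape[1]
        self.config = config or PEBConfig()
        self.level = level
        self.param_names = param_names
        self.Q = np.full(self.P, 1.0 / 64.0) if Q is None else np.asarray(Q, float)
        # informative default: implied per-unit effect has the Q scale
        if self.config.beta_prior_variance is None:
            col_norm2 = np.sum(X**2, axis=0)
            scale = self.U / col_norm2  # = 1 for a ones column, U for unit-norm
            self.beta_prior_var = np.concatenate([s * self.Q for s in scale])
        else:
            self.beta_prior_var = np.full(
                self.K * self.P, float(self.config.beta_prior_variance)
            )

    # -- internals ---------------------------------------------------------
    def _unit_terms(self, unit: _Unit, sig2: np.ndarray):
        """Per-unit (G, h, k): quadratic weight, information vector, constant.

        The unit's log-evidence contribution at second-level prediction
        r is  k - 0.5 r'G r + r'h  (r = X_i beta expanded over params).
        """
        if unit.mode == "raw":
            Ci = unit.S + np.diag(sig2)
            sign, ld = np.linalg.slogdet(Ci)
            if sign <= 0:
                return None
            G = np.linalg.inv(Ci)
            h = G @ unit.m
            k = -0.5 * (ld + float(unit.m @ h) + self.P * _LN2PI)
            return G, h, k
        R = np.diag(1.0 / sig2)
        Ps = unit.lam + R
        sign, ld_s = np.linalg.slogdet(Ps)
        if sign <= 0:
            return None
        M = np.linalg.inv(Ps)
        RM = R @ M
        G = R - RM @ R
        h = RM @ unit.c
        ld_r = -float(np.sum(np.log(sig2)))
        k = unit.k_const + 0.5 * (ld_r - ld_s) + 0.5 * float(unit.c @ M @ unit.c)
        return G, h, k

    def _posterior_and_evidence(self, gamma: float):
        sig2 = np.exp(-gamma) * self.Q
        A = np.diag(1.0 / self.beta_prior_var)
        b = np.zeros(self.K * self.P)
        k_sum = 0.0
        for i, unit in enumerate(self.units):
            terms = self._unit_terms(unit, sig2)
            if terms is None:
                return None
            G, h, k = terms
            x = self.X[i]
            A += np.kron(np.outer(x, x), G)
            b += np.kron(x, h)
            k_sum += k
        signA, ldA = np.linalg.slogdet(A)
        if signA <= 0:
            return None
        mu = np.linalg.solve(A, b)
        ld_prior = float(np.sum(np.log(self.beta_prior_var)))
        # integrate beta: k_sum + 0.5 b'mu - 0.5 ln|prior| - 0.5 ln|A|
        F = k_sum + 0.5 * float(b @ mu) - 0.5 * (ld_prior + ldA)
        lp = -0.5 * (gamma - self.config.gamma_hyper_mean) ** 2 / self.config.gamma_hyper_var
        return mu, A, F + lp

    def fit(self) -> PEBResults:
        cfg = self.config
        if cfg.fixed_gamma is not None:
            gamma = float(cfg.fixed_gamma)
        else:
            def neg(g):
                out = self._posterior_and_evidence(g)
                return np.inf if out is None else -out[2]

            res = minimize_scalar(
                neg, bounds=cfg.gamma_bounds, method="bounded",
                options={"xatol": 1e-3},
            )
            gamma = float(res.x)
        out = self._posterior_and_evidence(gamma)
        if out is None:
            raise SingularDesignError("degenerate second-level system")
        mu, A, F = out
        cov = np.linalg.inv(A)
        cov = 0.5 * (cov + cov.T)
        return PEBResults(
            beta=mu.reshape(self.K, self.P),
            beta_covariance=cov,
            design=self.X.copy(),
            gamma=gamma,
            between_var=np.exp(-gamma) * self.Q,
            free_energy=float(F),
            beta_prior_var=self.beta_prior_var.copy(),
            level=self.level,
            param_names=self.param_names,
            config=cfg,
            moments=(self.m.copy(), self.S.copy()),
        )


def fit_peb(
    first_level,
    X1,
    config: PEBConfig | None = None,
    Q: np.ndarray | None = None,
    level: str = "windows",
    block: str = "a",
    mode: str = "raw",
    param_names: list[str] | None = None,
) -> PEBResults:
    """Empirical-Bayes GLM on first-level posteriors (functional surface).

    ``mode="raw"`` treats (mean, covariance) pairs as pseudo-data;
    ``mode="bmr"`` scores units by the evidence change of swapping
    their own priors for the second-level prediction.
    """
    return PEB(first_level, X1, Q=Q, config=config, level=level, block=block,
               mode=mode, param_names=param_names).fit()


def _gauss_logpdf_at_zero(mean: np.ndarray, cov: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    return -0.5 * (ld + mean.size * _LN2PI + float(mean @ np.linalg.solve(cov, mean)))


def reduce_model(full: PEBResults, mask) -> ReducedModelEvidence:
    """Evidence change for retaining only the masked design columns.

    The reduced model fixes the beta blocks of excluded columns at zero;
    by the Savage-Dickey identity its log-evidence relative to the full
    model is ln p(beta_c = 0 | data) - ln p(beta_c = 0).
    """
    mask = np.asarray(mask, bool)
    if mask.size != full.K:
        raise ValueError("mask length must equal number of design columns")
    if not mask[0] and not full.config.allow_drop_constant:
        raise ValueError("mask excludes the constant column")
    drop = np.where(~mask)[0]
    if drop.size == 0:
        return ReducedModelEvidence(mask, 0.0)
    idx = np.concatenate([np.arange(full.n_params) + k * full.n_params for k in drop])
    mu_c = full.beta.ravel()[idx]
    cov_c = full.beta_covariance[np.ix_(idx, idx)]
    prior_c = np.diag(full.beta_prior_var[idx])
    dF = _gauss_logpdf_at_zero(mu_c, cov_c) - _gauss_logpdf_at_zero(
        np.zeros(idx.size), prior_c
    )
    return ReducedModelEvidence(mask, float(dF))


def compare_basis_subsets(
    full: PEBResults, always_keep_first: bool = True
) -> list[ReducedModelEvidence]:
    """Score all subsets of the non-constant design columns.

    Enumerates 2^(K-1) nested models (each retaining the constant
    column), scores each by Bayesian model reduction and attaches
    softmax posterior probabilities under a uniform model prior.
    """
    K = full.K
    free_cols = range(1, K) if always_keep_first else range(K)
    models = []
    for bits in itertools.product([True, False], repeat=len(list(free_cols))):
        mask = np.ones(K, bool)
        for col, keep in zip(range(1 if always_keep_first else 0, K), bits):
            mask[col] = keep
        models.append(reduce_model(full, mask))
    dF = np.array([m.delta_free_energy for m in models])
    p = np.exp(dF - dF.max())
    p /= p.sum()
    for m, pi in zip(models, p):
        m.posterior_probability = float(pi)
    return models


def residual_component(
    first_level,
    design,
    floor: float = 1e-4,
    block: str = "a",
) -> np.ndarray | None:
    """Moment-based estimate of the between-unit variance component.

    Per-parameter scatter of first-level means around the design fit
    (OLS residual mean square) minus the average stated within-unit
    variance, floored at a small positive value.  Anchoring the
    component to the observed scatter calibrates the second-level
    z-statistics when first-level posteriors understate their own
    variability (as MAR-based window summaries do).  Returns None when
    there are no residual degrees of freedom.
    """
    units = _extract_units(first_level, block)
    m = np.asarray([u.m for u in units])
    S = np.asarray([u.S for u in units])
    X = design.matrix if isinstance(design, TemporalBasisSet) else np.asarray(design, float)
    if X.ndim == 1:
        X = X[:, None]
    dof = m.shape[0] - X.shape[1]
    if dof < 2:
        return None
    B, *_ = np.linalg.lstsq(X, m, rcond=None)
    resid = m - X @ B
    scatter = (resid**2).sum(axis=0) / dof
    within = np.mean([np.diag(s) for s in S], axis=0)
    return np.maximum(scatter - within, floor)


def peb_of_peb(
    lower: list[PEBResults],
    X,
    Q: np.ndarray | None = None,
    config: PEBConfig | None = None,
    level: str = "sessions",
) -> PEBResults:
    """Recursive PEB: lower-level (beta, covariance) pairs as pseudo-data.

    With X a column of ones this yields session- or group-average
    effects; both expectations and covariances propagate upward.
    """
    shapes = {l.beta.shape for l in lower}
    if len(shapes) != 1:
        raise ValueError("lower-level beta layouts differ")
    if Q is None:
        Q = lower[0].beta_prior_var.copy()
    names = None
    if lower[0].param_names:
        names = [
            f"c{k}:{nm}" for k in range(lower[0].K) for nm in lower[0].param_names
        ]
    return PEB(lower, X, Q=Q, config=config, level=level, block="full",
               param_names=names).fit()


def iterative_peb_fit(
    window_data: list[CrossSpectralDensity],
    X1,
    prior_mean: np.ndarray,
    prior_covariance: np.ndarray,
    layout,
    inversion_config: InversionConfig | None = None,
    peb_config: PEBConfig | None = None,
    initial_fits: list[SpDCMResults] | None = None,
) -> tuple[PEBResults, list[SpDCMResults]]:
    """Alternate window-wise inversion and PEB with empirical priors.

    Each cycle (a) inverts every window CSD under the current priors,
    (b) fits the second-level GLM, and (c) rebuilds each window's prior:
    mean from the second-level prediction X1 beta (coupling block only),
    covariance from the estimated between-window covariance.  Cycling
    stops when the summed first-level free energy stops improving by
    more than ``cycle_tol`` or after ``max_cycles``; the best state is
    returned, so the recorded cycle trace is non-decreasing.
    """
    inv_cfg = inversion_config or InversionConfig()
    peb_cfg = peb_config or PEBConfig()
    base_Q = np.diag(prior_covariance)[layout.a_slice].copy()
    a_sl = layout.a_slice
    names = layout.names()[a_sl]

    pm = [prior_mean.copy() for _ in window_data]
    pc = [prior_covariance.copy() for _ in window_data]
    starts: list[np.ndarray | None] = [None] * len(window_data)

    best: tuple[PEBResults, list[SpDCMResults]] | None = None
    trace: list[float] = []
    Q = base_Q
    for _cycle in range(peb_cfg.max_cycles):
        if _cycle == 0 and initial_fits is not None:
            fits = list(initial_fits)
        else:
            fits = []
            for i, csd in enumerate(window_data):
                model = SpectralDCM(csd, pm[i], pc[i], layout, inv_cfg)
                fits.append(model.fit(start=starts[i]))
        peb = fit_peb(fits, X1, config=peb_cfg, Q=Q, param_names=names)
        sum_f1 = float(sum(f.free_energy for f in fits))
        if best is not None and sum_f1 <= trace[-1] + peb_cfg.cycle_tol:
            if sum_f1 > trace[-1]:
                best = (peb, fits)
                trace.append(sum_f1)
            break
        best = (peb, fits)
        trace.append(sum_f1)
        pred = peb.predicted_first_level()
        for i in range(len(window_data)):
            pm[i] = prior_mean.copy()
            pm[i][a_sl] = pred[i]
            pc[i] = prior_covariance.copy()
            di = np.arange(a_sl.start, a_sl.stop)
            pc[i][di, di] = peb.between_var
            starts[i] = fits[i].posterior_mean
    assert best is not None
    peb, fits = best
    peb.cycle_trace = trace  # type: ignore[attr-defined]
    return peb, fits
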