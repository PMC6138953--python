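"""Cross-spectral summaries of BOLD series via multivariate autoregression.

Observed data enter the model inversion only through their
cross-spectral density (CSD).  The CSD is obtained parametrically: a
multivariate autoregressive (MAR) model of order ``p`` is fitted by the
Yule-Walker moment equations (biased autocovariance normalisation, which
keeps the block-Toeplitz system positive semidefinite on short windows)
and converted to a spectral density on an arbitrary frequency grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import RegionalTimeSeries
from .errors import AliasedFrequencyError, DegenerateSeriesError

DEFAULT_MAR_ORDER = 4
DEFAULT_N_FREQ = 32


@dataclass
class MARModel:
    """MAR(p) model y(t) = sum_i a_i y(t-i) + z(t).

    coefficients : ndarray, shape (p, n, n)
    innovation_covariance : ndarray, shape (n, n), symmetric PSD
    """

    coefficients: np.ndarray
    innovation_covariance: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float)
        self.innovation_covariance = np.asarray(self.innovation_covariance, float)
        if self.coefficients.ndim != 3:
            raise ValueError("coefficients must have shape (p, n, n)")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("MAR coefficients must be finite")

    @property
    def order(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_regions(self) -> int:
        return self.coefficients.shape[1]


@dataclass
class CrossSpectralDensity:
    """Hermitian complex spectra on a strictly increasing frequency grid.

    values : ndarray, shape (F, n, n), complex
    kind : {"observed", "predicted"}
    """

    frequencies: np.ndarray
    values: np.ndarray
    kind: str = "observed"
    tr: float | None = None
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, float)
        self.values = np.asarray(self.values, complex)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.values.shape[0] != self.frequencies.size:
            raise ValueError("values/frequency length mismatch")

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def is_hermitian(self, tol: float = 1e-10) -> bool:
        vh = np.conj(np.transpose(self.values, (0, 2, 1)))
        scale = max(1.0, float(np.abs(self.values).max()))
        return bool(np.max(np.abs(self.values - vh)) <= tol * scale)

    def auto_spectra(self) -> np.ndarray:
        """Real auto-spectra, shape (F, n)."""
        return np.real(np.einsum("fii->fi", self.values))


def _autocovariance(y: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (1/N) lagged autocovariance C(k) = E[y(t+k) y(t)^T], k=0..max_lag."""
    n_scans, n = y.shape
    out = np.empty((max_lag + 1, n, n))
    for k in range(max_lag + 1):
        out[k] = y[k:].T @ y[: n_scans - k] / n_scans
    return out


def fit_mar(
    ts: RegionalTimeSeries | np.ndarray,
    order: int = DEFAULT_MAR_ORDER,
    tr: float | None = None,
    demean: bool = True,
    method: str = "yule-walker",
) -> MARModel:
    """Fit a MAR(p) by the multivariate Yule-Walker moment equations.

    ``method="least-squares"`` instead regresses y(t) on its p lags
    (conditional maximum likelihood) — offered for robustness checks;
    the moment estimator remains the default because its biased
    autocovariances guarantee a PSD innovation covariance on short
    windows.  Raises :class:`DegenerateSeriesError` when the system is
    singular (e.g. a constant channel).
    """
    if isinstance(ts, RegionalTimeSeries):
        y = ts.data
        tr = ts.tr
    else:
        y = np.asarray(ts, float)
        if y.ndim == 1:
            y = y[:, None]
        if tr is None:
            raise ValueError("tr required when passing a bare array")
    if order < 1:
        raise ValueError("order must be >= 1")
    n_scans, n = y.shape
    if n_scans <= 2 * order + 1:
        raise ValueError("series too short for requested MAR order")
    if demean:
        y = y - y.mean(axis=0, keepdims=True)

    if method in ("least-squares", "ls"):
        X = np.column_stack([y[order - k : n_scans - k] for k in range(1, order + 1)])
        Y = y[order:]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateSeriesError("degenerate series")
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        coeffs = np.stack(
            [B[i * n : (i + 1) * n].T for i in range(order)], axis=0
        )
        resid = Y - X @ B
        sigma = resid.T @ resid / resid.shape[0]
        return MARModel(coeffs, 0.5 * (sigma + sigma.T), tr)
    if method not in ("yule-walker", "yw"):
        raise ValueError(f"unknown MAR method: {method}")

    C = _autocovariance(y, order)  # C[k] = E[y(t+k) y(t)^T]

    def block(lag: int) -> np.ndarray:
        return C[lag] if lag >= 0 else C[-lag].T

    # Solve  sum_i a_i C(k-i) = C(k)  for k = 1..p,  transposed form
    # M @ [a_1^T; ...; a_p^T] = [C(1)^T; ...; C(p)^T],  M[k,i] = C(i-k).
    M = np.block([[block(i - k) for i in range(1, order + 1)] for k in range(1, order + 1)])
    G = np.concatenate([C[k].T for k in range(1, order + 1)], axis=0)

    eigs = np.linalg.eigvalsh(0.5 * (M + M.T))
    if not np.all(np.isfinite(M)) or eigs.min() < 1e-12 * max(eigs.max(), 1e-300):
        raise DegenerateSeriesError("degenerate series")
    try:
        AT = np.linalg.solve(M, G)
    except np.linalg.LinAlgError as exc:
        raise DegenerateSeriesError("degenerate series") from exc

    coeffs = np.stack(
        [AT[i * n : (i + 1) * n].T for i in range(order)], axis=0
    )
    sigma = C[0] - sum(coeffs[i - 1] @ block(-i) for i in range(1, order + 1))
    sigma = 0.5 * (sigma + sigma.T)
    # numerical floor: biased YW guarantees PSD up to round-off
    w, V = np.linalg.eigh(sigma)
    sigma = (V * np.clip(w, 0.0, None)) @ V.T
    return MARModel(coeffs, sigma, tr)


def default_frequency_grid(window_length: int, tr: float, n_freq: int = DEFAULT_N_FREQ) -> np.ndarray:
    """Linear grid from the window's resolvable frequency to Nyquist."""
    lo = 1.0 / (window_length * tr)
    hi = 1.0 / (2.0 * tr)
    return np.linspace(lo, hi, n_freq)


def mar_to_csd(
    mar: MARModel,
    frequencies: np.ndarray,
    tr: float | None = None,
    region_names: list[str] | None = None,
) -> CrossSpectralDensity:
    """Spectral density of a MAR model on the given frequencies (Hz).

    S(f) = tr * H(f) Sigma_z H(f)^H with
    H(f) = (I - sum_k a_k exp(-i 2 pi f tr k))^{-1}; the leading ``tr``
    makes S a density per Hz of the sampled process.
    """
    tr = mar.tr if tr is None else tr
    freqs = np.asarray(frequencies, float)
    nyq = 1.0 / (2.0 * tr)
    if np.any(freqs > nyq * (1 + 1e-12)):
        raise AliasedFrequencyError("aliased frequency")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    p, n = mar.order, mar.n_regions
    # phase factors: (F, p)
    z = np.exp(-2j * np.pi * freqs[:, None] * tr * np.arange(1, p + 1)[None, :])
    Af = np.tensordot(z, mar.coefficients, axes=(1, 0))  # (F, n, n)
    I = np.eye(n)
    H = np.linalg.solve(I[None] - Af, np.broadcast_to(I, (freqs.size, n, n)).copy())
    S = tr * H @ mar.innovation_covariance @ np.conj(np.transpose(H, (0, 2, 1)))
    S = 0.5 * (S + np.conj(np.transpose(S, (0, 2, 1))))
    return CrossSpectralDensity(freqs, S, kind="observed", tr=tr, region_names=region_names)


def observed_csd(
    ts: RegionalTimeSeries,
    frequencies: np.ndarray | None = None,
    order: int = DEFAULT_MAR_ORDER,
    demean: bool = True,
) -> CrossSpectralDensity:
    """Convenience: MAR-based observed CSD of one window."""
    if frequencies is None:
        frequencies = default_frequency_grid(ts.n_scans, ts.tr)
    mar = fit_mar(ts, order=order, demean=demean)
    return mar_to_csd(mar, frequencies, region_names=list(ts.region_names))
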