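"""The spDCM forward model and the nonlinear BOLD simulator.

Neuronal dynamics are linear, dx/dt = A x + v, driven by endogenous
fluctuations v with power-law ("pink" by default) spectral density
g_v(f) = alpha_v f^(-beta_v).  Observation runs through the canonical
balloon model (vasodilatory signal s, blood flow f, volume v,
deoxyhemoglobin q) whose linearisation around its fixed point yields a
per-region hemodynamic frequency response B(f).  The predicted BOLD
cross-spectrum is

    g_hat(f) = K(f) g_v(f) K(f)^H + g_e(f) I,
    K(f) = diag(B(f)) (i 2 pi f I - A_eff)^(-1),

with additive power-law observation noise g_e.  The simulator integrates
the same neuronal equation plus the *nonlinear* balloon equations at a
fine step, so the linearised estimator is tested against data it did not
generate itself.

Conventions: the simulator uses raw rate matrices (Hz, negative
diagonal); the estimator parameterises the diagonal as a log-scaling of
a fixed -0.5 Hz self-connection, A_eff[ii] = -0.5 exp(a_ii).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ConnectivityMatrix, RegionalTimeSeries
from .errors import UnstableSystemError
from .spectral import CrossSpectralDensity

# Balloon/BOLD constants (3T-appropriate; echo time TE in seconds).
TE = 0.04
V0 = 4.0
R0 = 25.0
THETA0 = 40.3

# Base amplitude scale for the power-law noise terms; log-deviations from
# this base are the estimated quantities.  The value keeps integrated
# neuronal fluctuations small enough that the balloon states stay inside
# their positive physiological domain.
ALPHA_BASE = 1.0 / 1024.0

# Reference (pivot) frequency of the power laws: g(f) = alpha (f/F_REF)^-beta,
# i.e. the amplitude is the spectral density at the centre of the
# resting-state band.
F_REF = 0.1


@dataclass
class HemodynamicParams:
    """Balloon-model rate constants (canonical resting values).

    signal_decay kappa (1/s), autoregulation gamma (1/s), transit time
    tau_h (s), vessel stiffness alpha, resting oxygen extraction E0 and
    intra/extravascular ratio epsilon.
    """

    kappa: float = 0.64
    gamma: float = 0.32
    transit: float = 2.0
    alpha: float = 0.32
    e0: float = 0.4
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.e0 < 1):
            raise ValueError("E0 must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        for v in (self.kappa, self.gamma, self.transit, self.epsilon):
            if v <= 0:
                raise ValueError("hemodynamic parameters must be positive")

    def bold_gains(self) -> tuple[float, float, float]:
        """BOLD signal-equation coefficients (k1, k2, k3)."""
        k1 = 4.3 * THETA0 * self.e0 * TE
        k2 = self.epsilon * R0 * self.e0 * TE
        k3 = 1.0 - self.epsilon
        return k1, k2, k3


@dataclass
class NoiseHyperparams:
    """Power-law amplitudes/exponents for neural and observation noise.

    Amplitudes are stored as positive numbers; the estimator works with
    log-deviations from ALPHA_BASE.  C (exogenous input weights) is kept
    as a zero placeholder: at rest u(t) = 0.
    """

    alpha_v: float = ALPHA_BASE
    beta_v: float = 1.0
    alpha_e: float = ALPHA_BASE
    beta_e: float = 1.0
    c_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        # estimation requires strictly positive amplitudes (log-parameterised);
        # exact zero is permitted only to drive noise-free simulations
        if self.alpha_v < 0 or self.alpha_e < 0:
            raise ValueError("noise amplitudes must be non-negative")


@dataclass(frozen=True)
class ParameterLayout:
    """Index bookkeeping for the flat parameter vector.

    Order: A block (n*n, row-major; diagonal entries are log-scalings),
    hemodynamic log-deviations (6 shared, or 6 per region when
    ``shared_hemodynamics`` is False), then 4 noise hyperparameters
    (log-amplitude deviation and exponent for neural, then observation
    noise).
    """

    n_regions: int
    shared_hemodynamics: bool = True

    @property
    def n_a(self) -> int:
        return self.n_regions**2

    @property
    def n_hemo(self) -> int:
        return 6 if self.shared_hemodynamics else 6 * self.n_regions

    @property
    def n_noise(self) -> int:
        return 4

    @property
    def n_params(self) -> int:
        return self.n_a + self.n_hemo + self.n_noise

    @property
    def a_slice(self) -> slice:
        return slice(0, self.n_a)

    @property
    def hemo_slice(self) -> slice:
        return slice(self.n_a, self.n_a + self.n_hemo)

    @property
    def noise_slice(self) -> slice:
        return slice(self.n_a + self.n_hemo, self.n_params)

    def a_indices(self) -> np.ndarray:
        return np.arange(self.n_a)

    def names(self) -> list[str]:
        n = self.n_regions
        out = [f"A[{i},{j}]" for i in range(n) for j in range(n)]
        hemo = ["kappa", "gamma", "transit", "alpha", "e0", "epsilon"]
        if self.shared_hemodynamics:
            out += [f"h_{h}" for h in hemo]
        else:
            out += [f"h_{h}[{r}]" for r in range(n) for h in hemo]
        out += ["ln_alpha_v", "beta_v", "ln_alpha_e", "beta_e"]
        return out


@dataclass
class DCMParams:
    """Structured view of one parameter vector.

    A uses the estimation convention (log-scaled diagonal); hemo holds
    the canonical centres (log-deviations live in the vector).
    """

    A: ConnectivityMatrix
    hemo: HemodynamicParams = field(default_factory=HemodynamicParams)
    noise: NoiseHyperparams = field(default_factory=NoiseHyperparams)

    def layout(self, shared_hemodynamics: bool = True) -> ParameterLayout:
        return ParameterLayout(self.A.n_regions, shared_hemodynamics)

    def to_vector(self, layout: ParameterLayout | None = None) -> np.ndarray:
        layout = layout or self.layout()
        ref = HemodynamicParams()
        hdev = np.log(
            np.array(
                [
                    self.hemo.kappa / ref.kappa,
                    self.hemo.gamma / ref.gamma,
                    self.hemo.transit / ref.transit,
                    self.hemo.alpha / ref.alpha,
                    self.hemo.e0 / ref.e0,
                    self.hemo.epsilon / ref.epsilon,
                ]
            )
        )
        if not layout.shared_hemodynamics:
            hdev = np.tile(hdev, layout.n_regions)
        noise = np.array(
            [
                np.log(self.noise.alpha_v / ALPHA_BASE),
                self.noise.beta_v,
                np.log(self.noise.alpha_e / ALPHA_BASE),
                self.noise.beta_e,
            ]
        )
        if self.A.convention != "log_scaled_diagonal":
            raise ValueError("DCMParams.A must use the log_scaled_diagonal convention")
        return np.concatenate([self.A.values.ravel(), hdev, noise])

    @classmethod
    def from_vector(cls, theta: np.ndarray, layout: ParameterLayout) -> "DCMParams":
        theta = np.asarray(theta, float)
        n = layout.n_regions
        A = ConnectivityMatrix(
            theta[layout.a_slice].reshape(n, n), "log_scaled_diagonal"
        )
        h = theta[layout.hemo_slice]
        if not layout.shared_hemodynamics:
            h = h[:6]  # structured view reports region 0
        ref = HemodynamicParams()
        hemo = HemodynamicParams(
            kappa=ref.kappa * np.exp(h[0]),
            gamma=ref.gamma * np.exp(h[1]),
            transit=ref.transit * np.exp(h[2]),
            alpha=min(ref.alpha * np.exp(h[3]), 0.999),
            e0=min(ref.e0 * np.exp(h[4]), 0.999),
            epsilon=ref.epsilon * np.exp(h[5]),
        )
        u = theta[layout.noise_slice]
        noise = NoiseHyperparams(
            alpha_v=ALPHA_BASE * np.exp(u[0]),
            beta_v=u[1],
            alpha_e=ALPHA_BASE * np.exp(u[2]),
            beta_e=u[3],
        )
        return cls(A, hemo, noise)


def default_priors(
    n_regions: int, shared_hemodynamics: bool = True
) -> tuple[np.ndarray, np.ndarray, ParameterLayout]:
    """Prior mean vector and (diagonal) covariance for the spDCM parameters.

    Off-diagonal couplings and diagonal log-scalings: N(0, 1/64).
    Hemodynamic log-deviations: N(0, 1/256).  Noise: log-amplitude
    deviations N(0, 1/4); power-law exponents N(1, 1/64) ("pink" at the
    prior mean).
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    layout = ParameterLayout(n_regions, shared_hemodynamics)
    mean = np.zeros(layout.n_params)
    var = np.empty(layout.n_params)
    var[layout.a_slice] = 1.0 / 64.0
    var[layout.hemo_slice] = 1.0 / 256.0
    mean[layout.noise_slice] = [0.0, 1.0, 0.0, 1.0]
    var[layout.noise_slice] = [1.0 / 4.0, 1.0 / 64.0, 1.0 / 4.0, 1.0 / 64.0]
    return mean, np.diag(var), layout


# ---------------------------------------------------------------------------
# Linearised forward model
# ---------------------------------------------------------------------------

def _effective_a(a_block: np.ndarray) -> np.ndarray:
    """Map estimation-convention A (..., n, n) to raw rates."""
    out = np.array(a_block, float, copy=True)
    n = out.shape[-1]
    idx = np.arange(n)
    out[..., idx, idx] = -0.5 * np.exp(out[..., idx, idx])
    return out


def _hemo_jacobian(kappa, gamma, transit, alpha, e0):
    """Jacobian of the balloon states (s, f, v, q) at the resting fixed point.

    Broadcasts over any leading shape of the parameter arrays.
    """
    shape = np.broadcast(kappa, gamma, transit, alpha, e0).shape
    J = np.zeros(shape + (4, 4))
    J[..., 0, 0] = -kappa
    J[..., 0, 1] = -gamma
    J[..., 1, 0] = 1.0
    J[..., 2, 1] = 1.0 / transit
    J[..., 2, 2] = -1.0 / (alpha * transit)
    J[..., 3, 1] = (1.0 + (1.0 - e0) * np.log1p(-e0) / e0) / transit
    J[..., 3, 2] = -(1.0 / alpha - 1.0) / transit
    J[..., 3, 3] = -1.0 / transit
    return J


def _hemo_output(e0, epsilon):
    """BOLD read-out gradient w.r.t. (s, f, v, q) at the fixed point."""
    k1 = 4.3 * THETA0 * e0 * TE
    k2 = epsilon * R0 * e0 * TE
    k3 = 1.0 - epsilon
    shape = np.broadcast(e0, epsilon).shape
    c = np.zeros(shape + (4,))
    c[..., 2] = V0 * (k2 - k3)
    c[..., 3] = -V0 * (k1 + k2)
    return c


def hemodynamic_transfer(
    frequencies: np.ndarray,
    kappa,
    gamma,
    transit,
    alpha,
    e0,
    epsilon,
) -> np.ndarray:
    """Frequency response of the linearised balloon model.

    Parameters may carry a leading batch (and region) shape; the result
    broadcasts to ``param_shape + (F,)``.
    """
    freqs = np.asarray(frequencies, float)
    J = _hemo_jacobian(kappa, gamma, transit, alpha, e0)  # (..., 4, 4)
    c = _hemo_output(e0, epsilon)  # (..., 4)
    iw = 2j * np.pi * freqs  # (F,)
    M = iw[:, None, None] * np.eye(4) - J[..., None, :, :]  # (..., F, 4, 4)
    b = np.zeros((4, 1))
    b[0, 0] = 1.0
    rhs = np.broadcast_to(b, M.shape[:-2] + (4, 1)).copy()
    sol = np.linalg.solve(M, rhs)  # (..., F, 4, 1)
    return np.einsum("...i,...fi->...f", c + 0j, sol[..., 0])


def _hemo_arrays(theta: np.ndarray, layout: ParameterLayout):
    """Hemodynamic parameter values from log-deviations; shape (B,) or (B, n)."""
    ref = HemodynamicParams()
    h = theta[:, layout.hemo_slice]
    if layout.shared_hemodynamics:
        dev = h  # (B, 6)
    else:
        dev = h.reshape(h.shape[0], layout.n_regions, 6)  # (B, n, 6)
    kappa = ref.kappa * np.exp(dev[..., 0])
    gamma = ref.gamma * np.exp(dev[..., 1])
    transit = ref.transit * np.exp(dev[..., 2])
    alpha = np.minimum(ref.alpha * np.exp(dev[..., 3]), 0.999)
    e0 = np.minimum(ref.e0 * np.exp(dev[..., 4]), 0.999)
    epsilon = ref.epsilon * np.exp(dev[..., 5])
    return kappa, gamma, transit, alpha, e0, epsilon


def csd_forward_batch(
    theta: np.ndarray, layout: ParameterLayout, frequencies: np.ndarray
) -> np.ndarray:
    """Predicted CSD for a batch of parameter vectors.

    theta : ndarray (B, P) -> returns complex ndarray (B, F, n, n).
    Unstable parameter vectors yield NaN slices rather than raising, so
    finite-difference callers can reject them gracefully.
    """
    theta = np.atleast_2d(np.asarray(theta, float))
    B = theta.shape[0]
    n = layout.n_regions
    freqs = np.asarray(frequencies, float)
    F = freqs.size

    A_eff = _effective_a(theta[:, layout.a_slice].reshape(B, n, n))
    iw = 2j * np.pi * freqs
    I = np.eye(n)
    M = iw[None, :, None, None] * I - A_eff[:, None]  # (B, F, n, n)
    R = np.linalg.solve(M, np.broadcast_to(I, (B, F, n, n)).copy())

    kappa, gamma, transit, alpha, e0, epsilon = _hemo_arrays(theta, layout)
    Bf = hemodynamic_transfer(freqs, kappa, gamma, transit, alpha, e0, epsilon)
    if layout.shared_hemodynamics:
        K = Bf[:, :, None, None] * R  # same scalar response for every region
    else:
        K = Bf.transpose(0, 2, 1)[:, :, :, None] * R  # (B, F, n, 1) * (B, F, n, n)

    u = theta[:, layout.noise_slice]
    fr = freqs[None] / F_REF
    gv = ALPHA_BASE * np.exp(u[:, 0, None]) * fr ** (-u[:, 1, None])
    ge = ALPHA_BASE * np.exp(u[:, 2, None]) * fr ** (-u[:, 3, None])
    KH = np.conj(np.transpose(K, (0, 1, 3, 2)))
    S = gv[:, :, None, None] * (K @ KH) + ge[:, :, None, None] * I
    # flag unstable draws (any eigenvalue with non-negative real part)
    stable = np.array([np.all(np.linalg.eigvals(a).real < 0) for a in A_eff])
    if not np.all(stable):
        S[~stable] = np.nan
    return S


def transfer_function(
    params: "DCMParams | np.ndarray",
    frequencies: np.ndarray,
    layout: ParameterLayout | None = None,
    include_hemodynamics: bool = True,
) -> CrossSpectralDensity:
    """Volterra-kernel frequency response K(f) of the full model.

    Returns a complex (F, n, n) array wrapped in a CrossSpectralDensity
    shell (kind="predicted") for convenient serialisation.  Raises
    :class:`UnstableSystemError` when A_eff is not stable.
    """
    if isinstance(params, DCMParams):
        layout = layout or params.layout()
        theta = params.to_vector(layout)
    else:
        if layout is None:
            raise ValueError("layout required with a bare parameter vector")
        theta = np.asarray(params, float)
    n = layout.n_regions
    freqs = np.asarray(frequencies, float)
    A_eff = _effective_a(theta[layout.a_slice].reshape(n, n))
    if np.any(np.linalg.eigvals(A_eff).real >= 0):
        raise UnstableSystemError("unstable system")
    iw = 2j * np.pi * freqs
    I = np.eye(n)
    M = iw[:, None, None] * I - A_eff[None]
    R = np.linalg.solve(M, np.broadcast_to(I, (freqs.size, n, n)).copy())
    if not include_hemodynamics:
        return CrossSpectralDensity(freqs, R, kind="predicted")
    kappa, gamma, transit, alpha, e0, epsilon = _hemo_arrays(theta[None], layout)
    Bf = hemodynamic_transfer(freqs, kappa, gamma, transit, alpha, e0, epsilon)[0]
    if layout.shared_hemodynamics:
        K = Bf[:, None, None] * R
    else:
        K = Bf.T[:, :, None] * R
    return CrossSpectralDensity(freqs, K, kind="predicted")


def predicted_csd(
    params: "DCMParams | np.ndarray",
    frequencies: np.ndarray,
    layout: ParameterLayout | None = None,
) -> CrossSpectralDensity:
    """Predicted BOLD cross-spectral density under the linearised model."""
    if isinstance(params, DCMParams):
        layout = layout or params.layout()
        theta = params.to_vector(layout)
    else:
        if layout is None:
            raise ValueError("layout required with a bare parameter vector")
        theta = np.asarray(params, float)
    A_eff = _effective_a(theta[layout.a_slice].reshape(layout.n_regions, layout.n_regions))
    if np.any(np.linalg.eigvals(A_eff).real >= 0):
        raise UnstableSystemError("unstable system")
    S = csd_forward_batch(theta[None], layout, frequencies)[0]
    S = 0.5 * (S + np.conj(np.transpose(S, (0, 2, 1))))
    return CrossSpectralDensity(np.asarray(frequencies, float), S, kind="predicted")


# ---------------------------------------------------------------------------
# Nonlinear simulator
# ---------------------------------------------------------------------------

def _powerlaw_noise(
    rng: np.random.Generator,
    n_steps: int,
    n_series: int,
    dt: float,
    amplitude: float,
    exponent: float,
) -> np.ndarray:
    """Gaussian noise with two-sided spectral density amplitude*|f|^-exponent.

    Realised by FFT-domain shaping of white noise; the zero-frequency
    component is removed.
    """
    w = rng.standard_normal((n_steps, n_series))
    W = np.fft.rfft(w, axis=0)
    f = np.fft.rfftfreq(n_steps, dt)
    scale = np.zeros_like(f)
    nz = f > 0
    scale[nz] = np.sqrt(amplitude * (f[nz] / F_REF) ** (-exponent) / dt)
    return np.fft.irfft(W * scale[:, None], n=n_steps, axis=0)


def _balloon_derivs(x, s, lf, lv, lq, hemo: HemodynamicParams):
    """Time derivatives of (s, ln f, ln v, ln q) given neuronal drive x."""
    f = np.exp(lf)
    v = np.exp(lv)
    q = np.exp(lq)
    E = 1.0 - (1.0 - hemo.e0) ** (1.0 / f)
    ds = x - hemo.kappa * s - hemo.gamma * (f - 1.0)
    dlf = s / f
    fv = v ** (1.0 / hemo.alpha)
    dlv = (f - fv) / (hemo.transit * v)
    dlq = (f * E / hemo.e0 - fv * q / v) / (hemo.transit * q)
    return ds, dlf, dlv, dlq


def simulate_bold(
    A_schedule: list[ConnectivityMatrix] | list[np.ndarray],
    hemo: HemodynamicParams,
    noise: NoiseHyperparams,
    scans_per_window: int,
    tr: float,
    seed: int,
    region_names: list[str] | None = None,
    oversample: int = 10,
    burn_in_scans: int = 32,
    amplitude_schedule: np.ndarray | None = None,
) -> RegionalTimeSeries:
    """Integrate the nonlinear generative model over a window schedule.

    For each window the neuronal rate matrix is the scheduled (raw-rate,
    stable) matrix; endogenous fluctuations are power-law shaped per
    window; balloon states evolve continuously across windows (fixed
    Euler step dt = tr/oversample, log-transformed positive states).
    Output is sampled every tr with power-law observation noise added.
    ``amplitude_schedule`` optionally scales the neural innovation
    amplitude per window (slow "arousal" nonstationarity).
    Deterministic given ``seed``.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    mats = []
    for m in A_schedule:
        a = m.effective_rate() if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
        if np.any(np.linalg.eigvals(a).real >= 0):
            raise UnstableSystemError("unstable matrix in schedule")
        mats.append(a)
    n = mats[0].shape[0]
    rng = np.random.default_rng(seed)
    dt = tr / oversample
    steps_per_window = scans_per_window * oversample

    # balloon states at the resting fixed point; neuronal state at zero
    x = np.zeros(n)
    s = np.zeros(n)
    lf = np.zeros(n)
    lv = np.zeros(n)
    lq = np.zeros(n)

    k1, k2, k3 = hemo.bold_gains()

    def bold(lv, lq):
        v = np.exp(lv)
        q = np.exp(lq)
        return V0 * (k1 * (1 - q) + k2 * (1 - q / v) + k3 * (1 - v))

    # burn-in under the first scheduled matrix, discarded
    burn_steps = burn_in_scans * oversample
    if noise.alpha_v > 0:
        v_burn = _powerlaw_noise(rng, burn_steps, n, dt, noise.alpha_v, noise.beta_v)
    else:
        v_burn = np.zeros((burn_steps, n))

    def integrate(A, innov, record_every=None):
        # Heun (predictor-corrector) steps; the innovation is treated as a
        # piecewise-constant forcing over each step.  Trajectories that
        # escape the physiological domain produce non-finite states and
        # are rejected by the output check, so numeric warnings here are
        # expected noise.
        nonlocal x, s, lf, lv, lq
        recorded = []
        for t in range(innov.shape[0]):
            ds, dlf, dlv, dlq = _balloon_derivs(x, s, lf, lv, lq, hemo)
            dx = A @ x + innov[t]
            xp = x + dt * dx
            sp = s + dt * ds
            lfp = lf + dt * dlf
            lvp = lv + dt * dlv
            lqp = lq + dt * dlq
            ds2, dlf2, dlv2, dlq2 = _balloon_derivs(xp, sp, lfp, lvp, lqp, hemo)
            dx2 = A @ xp + innov[t]
            x = x + 0.5 * dt * (dx + dx2)
            s = s + 0.5 * dt * (ds + ds2)
            lf = lf + 0.5 * dt * (dlf + dlf2)
            lv = lv + 0.5 * dt * (dlv + dlv2)
            lq = lq + 0.5 * dt * (dlq + dlq2)
            if record_every and (t + 1) % record_every == 0:
                recorded.append(bold(lv, lq))
        return recorded

    if amplitude_schedule is None:
        amplitude_schedule = np.ones(len(mats))
    samples = []
    with np.errstate(all="ignore"):
        integrate(mats[0], v_burn)
        for A, amp in zip(mats, amplitude_schedule):
            innov = _powerlaw_noise(rng, steps_per_window, n, dt,
                                    amp * noise.alpha_v, noise.beta_v) \
                if noise.alpha_v > 0 else np.zeros((steps_per_window, n))
            samples.extend(integrate(A, innov, record_every=oversample))

    y = np.asarray(samples)
    if not np.all(np.isfinite(y)):
        raise ValueError(
            "simulation left the physiological domain (non-finite balloon states); "
            "reduce the innovation amplitude"
        )
    n_scans = y.shape[0]
    if noise.alpha_e > 0:
        y = y + _powerlaw_noise(rng, n_scans, n, tr, noise.alpha_e, noise.beta_e)
    names = region_names or [f"R{i}" for i in range(n)]
    return RegionalTimeSeries(y, tr, names)
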