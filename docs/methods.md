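# Methods

`dynspdcm` estimates *dynamic effective connectivity* from resting-state
BOLD time series: the directed coupling matrix A (Hz) among brain
regions is decomposed into a baseline component A0 that is conserved
over a session and dynamic components A(k) that are expressed on
temporal basis functions over sliding windows,

    A_i = A0 + sum_k A(k) X_k(i),        i = 1..W windows.

This note records the model, the estimation machinery, the synthetic
data used to exercise it, and the numerical and design choices a
maintainer would want to know.

## Generative model (per window)

Neuronal dynamics are linear and stochastic,

    dx/dt = A x + v,

with endogenous fluctuations v whose spectral density is a power law
g_v(f) = alpha_v (f/f0)^(-beta_v).  The pivot f0 = 0.1 Hz sits at the
centre of the resting-state band, so the amplitude is "density in the
band of interest".  Without a pivot (density alpha f^-beta referenced
to 1 Hz), any amplitude large enough to matter integrates to neuronal
variance of order one over the BOLD band, which is outside the
observation model's domain — see *Simulator* below.

Observation runs through the balloon model per region: vasodilatory
signal s, inflow f, volume v, deoxyhemoglobin q,

    ds/dt = x - kappa s - gamma (f - 1)
    df/dt = s
    tau dv/dt = f - v^(1/alpha)
    tau dq/dt = f E(f)/E0 - v^(1/alpha) q / v,     E(f) = 1-(1-E0)^(1/f)

with BOLD = V0 [k1 (1-q) + k2 (1-q/v) + k3 (1-v)], k1 = 4.3 theta0 E0 TE,
k2 = epsilon r0 E0 TE, k3 = 1 - epsilon, at 3 T-appropriate constants
(theta0 = 40.3 s^-1, r0 = 25 s^-1, TE = 40 ms, V0 = 4).  Defaults:
kappa = 0.64 s^-1, gamma = 0.32 s^-1, tau = 2 s, alpha = 0.32,
E0 = 0.4, epsilon = 1; hemodynamics are shared across regions by
default (configurable per region).

The predicted cross-spectral density (CSD) of the observed signal is

    g_hat(f) = K(f) g_v(f) K(f)^H + g_e(f) I,
    K(f) = diag(B(f)) (i 2 pi f I - A_eff)^(-1),

where B(f) is the transfer function of the balloon model linearised at
its resting fixed point and g_e is power-law observation noise.
Estimation parameterises the diagonal of A as the log-scaling of a
fixed -0.5 Hz self-connection, A_eff[ii] = -0.5 exp(a_ii), so
stability is soft-encoded; off-diagonals are free rates in Hz.

Priors: coupling entries N(0, 1/64); hemodynamic log-deviations
N(0, 1/256); noise log-amplitude deviations N(0, 1/4) around the base
amplitude 1/1024 and exponents N(1, 1/64) ("pink" at the mean).

## Observed data: MAR-based cross-spectra

Each window (rectangular, demeaned; trailing partial windows dropped)
is summarised by a fourth-order multivariate autoregressive model
fitted with the Yule–Walker moment equations (biased 1/N
autocovariances keep the block-Toeplitz system PSD on short windows)
and converted to a CSD on 32 linearly spaced frequencies from the
window's resolvable frequency 1/(L·TR) to Nyquist.

## Variational Laplace inversion

The data vector stacks, per frequency, the real parts of the upper
triangle (diagonal included) and imaginary parts of the strict upper
triangle — no Hermitian-redundant entry is counted twice.  Sampling
error is Gaussian and *heteroscedastic*: each entry carries a fixed
scale sqrt(S_ii S_jj) from the observed auto-spectra (the asymptotic
standard error of a cross-spectral estimate), floored at 1% of the
spectral peak so that near-zero high-frequency entries (where the
low-order MAR's rational form leaves a spectral floor) are
down-weighted.  One log-precision per block (auto vs cross spectra)
scales these, with a weak Gaussian hyperprior N(0, 32).  Without the
heteroscedastic scales, the ~5-decade dynamic range of BOLD spectra
means only the few largest low-frequency entries inform the fit.

Optimisation is Gauss–Newton ascent on the Laplace free energy with
Levenberg–Marquardt damping (central finite-difference Jacobians,
batched through the vectorised forward model).  A parameter step is
accepted only if the fully re-evaluated free energy increases, so the
trace is non-decreasing by construction; noise log-precisions are
updated by damped Newton steps under the same rule.  Defaults: stop
when |dF| < 1e-2 on 4 consecutive iterations, max 128 iterations.  The
optimiser is deterministic; within-model, noiseless recovery of the
benchmark coupling matrix is exact to ~1e-3, and posterior coverage is
calibrated when the data follow the model's own error law (95%
intervals cover ~100% at 20 replicates in the test suite).

## Hierarchical PEB

Second level: window posterior means m_i of the coupling block are
modelled as m_i ~ N(X_i beta, S_i + Sigma2) with S_i the within-window
posterior covariance and Sigma2 = exp(-gamma) Q a single scaled
covariance component.  For fixed gamma the model is linear-Gaussian
(closed-form posterior over beta and marginal likelihood); gamma is
optimised by bounded scalar search in [-8, 8] under a N(0, 1)
hyperprior.  Two input modes exist: raw (mean, covariance) pairs as
pseudo-data — the default, also used when stacking PEB levels
recursively across sessions and subjects — and a precision-space
Bayesian-model-reduction mode that first removes each unit's own prior
(used for diagnostics; both coincide when the data evidence is full
rank).

The default prior on second-level effects scales the component Q so
that the implied *per-window* effect has the first-level prior scale
(for unit-norm design columns this is W·Q).  Bayesian model reduction
over design columns uses the Savage–Dickey identity — exact for
point-zero reductions with a factorised prior — and all 2^(K-1)
subsets retaining the constant column are scored with softmax
posterior probabilities under a uniform model prior.

**Iterative empirical priors.**  The window inversions and the PEB are
alternated: after each pass, every window's prior mean on the coupling
block is set to the second-level prediction X_i beta and its prior
covariance to the estimated between-window covariance, and the windows
are re-inverted (warm-started).  Cycling stops when the summed
first-level free energy improves by less than 0.25 nats or after 8
cycles; the best state is kept, so the recorded cycle trace is
non-decreasing.  (The second-level marginal likelihood is *not* used
as the cycle objective: the units' priors change between cycles, so it
is not comparable across them.)

**Calibration and circularity.**  Two facts shape the analysis layout:

1. MAR-based window summaries understate their own sampling
   variability: the stated posterior sd of coupling entries is ~0.05
   while the realised between-window scatter is ~0.17 on the benchmark.
   The between-window component used for *model comparison* is
   therefore calibrated to the observed residual scatter (OLS residual
   mean square under the full design, minus the stated within-window
   variance, floored at 1e-4).
2. Empirically re-prioritised windows echo the second-level
   prediction, including its dynamic columns.  Model comparison on
   such fits lets the second level confirm patterns it fed downward
   (measured: stationary data "detect" dynamics with probability ~1
   after a few cycles).  Comparison is therefore computed from the
   first-pass fits (inverted under default priors), while parameter
   estimates — the baseline A0, the window-wise coupling estimates and
   their principal eigenvariate — come from the iterated fits, which
   is the published procedure for those quantities.

## Synthetic data

The face-validity benchmark is a 4-node network with fixed printed
baseline and dynamic coupling matrices.  Stationary datasets use the
baseline alone; nonstationary datasets modulate the dynamic matrix by
the unit-norm first DCT harmonic across 15 windows of 200 scans at
TR = 0.72 s.  Innovations and observation noise are pink (beta = 1)
with amplitudes alpha_v = alpha_e = 1/1024 at the 0.1 Hz pivot.  The
amplitude was fixed by a structural constraint: the balloon model has
no equilibrium for sustained neuronal drive x < -gamma = -0.32
(steady-state flow gain 1/gamma), and pink innovations at amplitudes
1/16…1/512 wander across that threshold (1/256 diverges on 4/10 seeds;
1/1024 is stable across 120 runs of both scenarios).  Integration is
Heun (predictor–corrector) at dt = TR/10 with log-transformed positive
states; innovations are FFT-shaped white noise per window; the
simulator is bit-deterministic given its seed.

The multi-session cohort generator shares the benchmark baseline
across sessions but gives each session its own dynamic coupling mode
(zero-diagonal Gaussian, scale 0.2, full-swing cosine schedule) *and*
slow window-to-window innovation-amplitude drift (log-normal, sd 0.5,
clipped to [0.5, 1.8]).  The drift emulates arousal/vigilance
nonstationarity of real sessions; it matters because zero-mean
coupling dynamics alone average out of whole-series estimates almost
completely, leaving stationary fits nearly as consistent across
sessions as windowed baselines.

What the synthetic data do *not* emulate: head motion, physiological
(cardiac/respiratory) aliasing, scanner drift, regional heterogeneity
of hemodynamics, and the empirical spatial covariance of real DMN
recordings.  Passing tests therefore certify the estimation machinery
and its calibration on well-specified inputs, not performance on real
rsfMRI.

## Known limitations

* **Detection power at the benchmark's noise level.**  Window-level
  coupling estimates from 144-s windows carry irreducible sampling
  noise of ~0.17 per element (invariant to MAR order, frequency grid,
  error-scale floors, prior tightening and detrending; the optimiser is
  verified globally stable by multistart, and within-model recovery is
  exact).  The benchmark's dynamic effect peaks at 0.105 per element,
  so the evidence for the dynamic component totals only ~6–8 nats
  against an Occam cost of ~8–20 nats: nested-model comparison detects
  the *absence* of dynamics reliably (constant-only wins on stationary
  data in ≥9/10 seeds) but detects their *presence* in only a minority
  of seeds, and the eigenvariate–cosine correlation has median
  |r| ≈ 0.4 across seeds.  Larger innovation amplitudes would not
  help — the noise is relative — and stronger modulation would change
  the benchmark.  The acceptance script reports the honest value.
* Laplace posteriors are exactly calibrated only under the model's own
  (floored, block-precision) error law; under other noise laws shared
  block precisions misweight entries and intervals can be ~1.4x
  overconfident.
* The fPCA basis implements the smoothness penalty only (no
  supervision or sparsity), with GCV on a fixed log-spaced grid for
  the "auto" weight.
* Windows are rectangular; no tapering is applied.
* Exogenous inputs are fixed at zero (rest); the input-weight matrix C
  is carried as a placeholder only.

## Problem sizes used by the test suite

The suite runs the full 4-node benchmark (two datasets × 10 seeds),
a one-subject four-session cohort (two seeds), a 50,000-scan
simulation for the linearisation oracle, and 20 replicate inversions
for the coverage check; unit tests use 2-region toys throughout.
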