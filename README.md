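# dynspdcm

Dynamic effective connectivity from resting-state fMRI, by spectral
dynamic causal modelling (spDCM) with hierarchical parametric
empirical Bayes (PEB).

Functional connectivity (correlation between regional BOLD signals)
fluctuates over minutes within a resting-state scan, but correlations
say nothing about the direction of influence between regions.  This
package estimates *directed* coupling and its dynamics: regional BOLD
series are segmented into sliding windows; each window is summarised
by its cross-spectral density g(f) (via a fourth-order Yule–Walker MAR
model) and inverted under a biophysical generative model

    dx/dt = A x + v,      y = h(x, theta_h) + e,
    g_hat(f) = K(f) g_v(f) K(f)^H + g_e(f) I,

where A (Hz) is the effective connectivity, h the balloon hemodynamic
model with linearised frequency response K(f), and g_v, g_e power-law
("pink") neural and observation noise spectra.  Inversion is
variational Laplace: Gauss–Newton ascent on a free-energy bound,
returning a Gaussian posterior over (A, hemodynamic, noise) parameters
and a log-evidence proxy.

Window-wise posteriors then enter a second-level linear model over a
temporal basis set X (constant, DCT harmonics, PCA or
smoothness-penalised functional-PCA eigenvariates of the window
estimates),

    A_i = A0 + sum_k A(k) X_k(i),

fitted by parametric empirical Bayes with iterative empirical priors.
Bayesian model reduction (Savage–Dickey) scores every subset of basis
functions; recursive PEB propagates posteriors across sessions and
subjects.  The output separates a baseline connectivity A0 —
reproducible across sessions — from dynamic components that fluctuate
within a session.

Intended users: neuroimaging methods researchers who want a compact,
dependency-light reference implementation of windowed spDCM + PEB with
a fully synthetic, self-contained validation suite.

## Worked example

Simulate a nonstationary 4-node dataset whose coupling follows
A_i = A0 + A1·cos-schedule across 15 windows, analyse it, and compare
the nested second-level models:

```python
import numpy as np
from dynspdcm import (make_benchmark_scenario, segment_windows, WindowingScheme,
                      default_priors, iterative_peb_fit, make_dct_basis)
from dynspdcm.spectral import observed_csd, default_frequency_grid

scenario = make_benchmark_scenario("dynamic", seed=7)
ts = scenario.simulate()                      # 3000 scans x 4 regions, TR 0.72 s
windows = segment_windows(ts, WindowingScheme(200, 0))
freqs = default_frequency_grid(200, ts.tr)
csds = [observed_csd(w, freqs, order=4) for w in windows]

pm, pc, layout = default_priors(4)
peb, fits = iterative_peb_fit(csds, make_dct_basis(len(windows), 2), pm, pc, layout)
print(peb.summary())
```

which prints (seed 7):

```
PEB (windows); units: 15, design columns: 2
  free energy: -84.68 nats
  between-unit log-precision gamma: -1.552  (variance scale 4.7194)
  column 0: A[1,1]=-1.455±0.251, A[2,2]=-1.296±0.254, A[0,2]=1.026±0.240, A[0,0]=-0.976±0.252
  column 1: A[2,2]=1.409±0.258, A[0,2]=-0.751±0.241, A[0,3]=-0.504±0.242, A[2,0]=0.367±0.239
```

Column 0 is the baseline A0 times the unit-norm constant regressor
(divide by sqrt(15) for per-window units): the strongest off-diagonal
baseline entry, A[0,2] = 1.026/sqrt(15) = 0.265 Hz, recovers the
generating value 0.294 Hz; negative diagonal entries are log-scalings
of the −0.5 Hz self-connection.  Column 1 is the cosine-locked dynamic
component; its strongest off-diagonal entry A[0,2] = −0.75 has the
sign and location of the generator's largest dynamic coupling
(−0.27), though individual entries are noisy at this window length.
The principal eigenvariate of the window estimates tracks the
generating cosine:

```python
from dynspdcm.simulation import principal_eigenvariate
from dynspdcm.bases import dct_column
a = np.array([f.posterior_mean[layout.a_slice] for f in fits])
u = principal_eigenvariate(a)
print(abs(np.corrcoef(u, dct_column(15, 1))[0, 1]))   # 0.87 for this seed
```

The full experiment — both stationary and dynamic datasets, model
comparison, eigenvariate recovery — is one call
(`dynspdcm.run_face_validity(seed)`) or one CLI command:

```sh
dynspdcm face-validity --seed 7 --out report.json
```

Other CLI entry points: `dynspdcm simulate`, `fit-session`,
`fit-group`, `compare-models`.

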