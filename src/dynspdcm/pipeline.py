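"""End-to-end orchestration: windows -> session PEB -> sessions -> subjects.

A session analysis segments the series, inverts a spectral DCM per
window with iterative empirical priors, and fits the second-level model
under the requested temporal basis.  Data-driven bases (PCA/fPCA) need
first-level estimates, so a first pass runs under the average model and
its window posteriors seed the basis; a second pass then refits.
Recursive PEB averages sessions within subject (X2 = ones) and subjects
within group (X3 = ones), propagating means and covariances upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bases import make_average_basis, make_dct_basis, make_fpca_basis, make_pca_basis
from .data import (
    RegionalTimeSeries,
    WindowingScheme,
    cross_session_similarity,
    segment_windows,
)
from .generative import default_priors
from .inversion import InversionConfig, SpDCMResults, fit_spdcm
from .peb import PEBConfig, PEBResults, iterative_peb_fit, peb_of_peb
from .spectral import default_frequency_grid, observed_csd

logger = logging.getLogger("dynspdcm")


@dataclass
class StudyConfig:
    """Study-wide analysis settings."""

    window_length: int = 200
    overlap: int = 100
    basis: str = "dct"
    K: int = 6
    mar_order: int = 4
    n_freq: int = 32
    fpca_smoothness: float | str = "auto"
    shared_hemodynamics: bool = True
    inversion: InversionConfig = field(default_factory=InversionConfig)
    peb: PEBConfig = field(default_factory=PEBConfig)
    seed: int = 0

    def scheme(self) -> WindowingScheme:
        return WindowingScheme(self.window_length, self.overlap)


@dataclass
class SessionResult:
    peb: PEBResults
    window_fits: list[SpDCMResults]
    basis_kind: str
    stationary_fit: SpDCMResults | None = None

    def baseline(self) -> np.ndarray:
        return self.peb.baseline_matrix()


@dataclass
class SubjectResult:
    sessions: list[SessionResult]
    session_average: PEBResults
    similarity_dynamic: float | None
    similarity_stationary: float | None


@dataclass
class GroupResult:
    subjects: dict[str, SubjectResult]
    group_average: PEBResults
    n_regions: int

    def edge_mask(self, level: float = 0.95) -> np.ndarray:
        """Baseline edges whose posterior interval excludes zero.

        Widening the interval can only remove edges (monotone rule).
        The baseline block is the first n^2 entries of the propagated
        parameter vector (constant column of the window-level design).
        """
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        nsq = self.n_regions**2
        b = self.group_average.beta.ravel()[:nsq]
        sd = np.sqrt(np.diag(self.group_average.beta_covariance))[:nsq]
        return ((np.abs(b) - z * sd) > 0).reshape(self.n_regions, self.n_regions)

    def similarity_table(self) -> dict[str, dict[str, float | None]]:
        return {
            sid: {
                "dynamic": s.similarity_dynamic,
                "stationary": s.similarity_stationary,
            }
            for sid, s in self.subjects.items()
        }

    def model_comparison(self) -> dict[int, dict[str, float]]:
        """Reduced-model scores pooled over all sessions.

        For every subset of the non-constant design columns, reports
        the winning-model frequency across sessions, the fixed-effects
        evidence (summed delta-F over sessions), and its softmax
        posterior probability.
        """
        table: dict[int, dict[str, float]] = {}
        for subj in self.subjects.values():
            for sess in subj.sessions:
                models = sess.peb.compare_subsets()
                best = max(models, key=lambda m: m.posterior_probability)
                for m in models:
                    row = table.setdefault(
                        m.model_id, {"wins": 0.0, "summed_delta_f": 0.0}
                    )
                    row["summed_delta_f"] += m.delta_free_energy
                    if m.model_id == best.model_id:
                        row["wins"] += 1.0
        dfs = np.array([row["summed_delta_f"] for row in table.values()])
        probs = np.exp(dfs - dfs.max())
        probs /= probs.sum()
        for row, p in zip(table.values(), probs):
            row["posterior_probability"] = float(p)
        return table


def _make_basis(kind: str, W: int, K: int, first_level=None, smoothness="auto"):
    K = min(K, W)
    if kind == "average":
        return make_average_basis(W)
    if kind == "dct":
        return make_dct_basis(W, K)
    if kind == "pca":
        return make_pca_basis(first_level, K)
    if kind == "fpca":
        return make_fpca_basis(first_level, K, smoothness)
    raise ValueError(f"unknown basis kind: {kind}")


def run_session_analysis(
    ts: RegionalTimeSeries,
    config: StudyConfig,
    fit_stationary: bool = False,
) -> SessionResult:
    """Windowed dynamic-connectivity analysis of one session."""
    windows = segment_windows(ts, config.scheme())
    W = len(windows)
    freqs = default_frequency_grid(config.window_length, ts.tr, config.n_freq)
    csds = [observed_csd(w, freqs, order=config.mar_order) for w in windows]
    pm, pc, layout = default_priors(ts.n_regions, config.shared_hemodynamics)

    if config.basis in ("pca", "fpca"):
        logger.info("first pass (average model) for data-driven basis")
        _, pass_one = iterative_peb_fit(
            csds, make_average_basis(W), pm, pc, layout,
            inversion_config=config.inversion, peb_config=config.peb,
        )
        first_means = [f.posterior_mean[layout.a_slice] for f in pass_one]
        basis = _make_basis(config.basis, W, config.K, first_means, config.fpca_smoothness)
    else:
        basis = _make_basis(config.basis, W, config.K)

    peb, fits = iterative_peb_fit(
        csds, basis, pm, pc, layout,
        inversion_config=config.inversion, peb_config=config.peb,
    )
    logger.info("session PEB free energy: %.2f", peb.free_energy)

    stationary = None
    if fit_stationary:
        full_csd = observed_csd(
            ts, default_frequency_grid(ts.n_scans, ts.tr, config.n_freq),
            order=config.mar_order,
        )
        stationary = fit_spdcm(full_csd, pm, pc, layout, config.inversion)
    return SessionResult(peb, fits, basis.kind, stationary)


def run_group_analysis(
    subjects: dict[str, list[RegionalTimeSeries]],
    config: StudyConfig,
) -> GroupResult:
    """Per-session analyses, session averaging, and group-level PEB.

    For every subject the cross-session similarity of the dynamic-model
    baseline A0 is compared with that of whole-series stationary fits.
    """
    subject_results: dict[str, SubjectResult] = {}
    subject_averages: list[PEBResults] = []
    for sid, sessions in subjects.items():
        session_results = []
        for k, ts in enumerate(sessions):
            logger.info("subject %s session %d", sid, k)
            session_results.append(run_session_analysis(ts, config, fit_stationary=True))
        ones = np.ones((len(session_results), 1))
        avg = peb_of_peb([s.peb for s in session_results], ones, level="sessions")
        sim_dyn = sim_stat = None
        if len(session_results) >= 2:
            sim_dyn = cross_session_similarity([s.baseline() for s in session_results])
            stat_mats = [
                s.stationary_fit.a_matrix().values
                for s in session_results
                if s.stationary_fit is not None
            ]
            if len(stat_mats) >= 2:
                sim_stat = cross_session_similarity(stat_mats)
        subject_results[sid] = SubjectResult(session_results, avg, sim_dyn, sim_stat)
        subject_averages.append(avg)

    ones = np.ones((len(subject_averages), 1))
    group = peb_of_peb(subject_averages, ones, level="subjects")
    n_regions = next(iter(subjects.values()))[0].n_regions
    return GroupResult(subject_results, group, n_regions)
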