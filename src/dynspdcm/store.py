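"""HDF5 result store: one group per analysis level.

Layout:
    /windows/<i>/posterior_mean, posterior_covariance, free_energy, trace
    /windows/<i>/csd/{frequencies, real, imag}
    /peb/{beta, beta_covariance, design, gamma, between_var, free_energy}
Complex spectra are stored as separate real/imaginary datasets.
"""

from __future__ import annotations

import os

import h5py
import numpy as np

from .inversion import SpDCMResults
from .peb import PEBResults
from .spectral import CrossSpectralDensity


def _write_csd(grp: h5py.Group, csd: CrossSpectralDensity) -> None:
    grp.create_dataset("frequencies", data=csd.frequencies)
    grp.create_dataset("real", data=csd.values.real)
    grp.create_dataset("imag", data=csd.values.imag)
    grp.attrs["kind"] = csd.kind
    if csd.tr is not None:
        grp.attrs["tr"] = csd.tr


def _write_fit(grp: h5py.Group, fit: SpDCMResults) -> None:
    grp.create_dataset("posterior_mean", data=fit.posterior_mean)
    grp.create_dataset("posterior_covariance", data=fit.posterior_covariance)
    grp.create_dataset("trace", data=np.asarray(fit.trace))
    grp.create_dataset("lambdas", data=fit.lambdas)
    grp.attrs["free_energy"] = fit.free_energy
    grp.attrs["status"] = fit.status
    grp.attrs["n_iter"] = fit.n_iter
    _write_csd(grp.create_group("csd"), fit.observed)


def _write_peb(grp: h5py.Group, peb: PEBResults) -> None:
    grp.create_dataset("beta", data=peb.beta)
    grp.create_dataset("beta_covariance", data=peb.beta_covariance)
    grp.create_dataset("design", data=peb.design)
    grp.create_dataset("between_var", data=peb.between_var)
    grp.create_dataset("beta_prior_var", data=peb.beta_prior_var)
    grp.attrs["gamma"] = peb.gamma
    grp.attrs["free_energy"] = peb.free_energy
    grp.attrs["level"] = peb.level


def save_session(path: str | os.PathLike, peb: PEBResults,
                 window_fits: list[SpDCMResults]) -> None:
    """Write one session's PEB and window inversions to HDF5."""
    with h5py.File(path, "w") as fh:
        _write_peb(fh.create_group("peb"), peb)
        wins = fh.create_group("windows")
        for i, fit in enumerate(window_fits):
            _write_fit(wins.create_group(str(i)), fit)


def load_session(path: str | os.PathLike) -> dict:
    """Read back the arrays of a stored session (plain dict of arrays)."""
    out: dict = {"windows": []}
    with h5py.File(path, "r") as fh:
        g = fh["peb"]
        out["peb"] = {
            "beta": g["beta"][()],
            "beta_covariance": g["beta_covariance"][()],
            "design": g["design"][()],
            "between_var": g["between_var"][()],
            "gamma": g.attrs["gamma"],
            "free_energy": g.attrs["free_energy"],
            "level": g.attrs["level"],
        }
        wins = fh["windows"]
        for key in sorted(wins, key=int):
            w = wins[key]
            out["windows"].append(
                {
                    "posterior_mean": w["posterior_mean"][()],
                    "posterior_covariance": w["posterior_covariance"][()],
                    "free_energy": w.attrs["free_energy"],
                    "trace": w["trace"][()],
                    "csd_frequencies": w["csd/frequencies"][()],
                    "csd": w["csd/real"][()] + 1j * w["csd/imag"][()],
                }
            )
    return out
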