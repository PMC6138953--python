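"""Containers and I/O for regional BOLD time series and connectivity matrices.

Time series are plain delimited text (one header row of region names,
one row per scan).  Windowing is rectangular and non-padded: offsets
advance by ``window_length - overlap`` and trailing scans that do not
fill a complete window are dropped, because the spectral summaries
downstream require full-length windows.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRegionError,
    EmptyTimeSeriesError,
    MissingFileError,
    NonNumericCellError,
    RaggedRowsError,
    WindowExceedsSeriesError,
)


@dataclass
class RegionalTimeSeries:
    """A scans x regions matrix of BOLD samples with its sampling interval.

    Parameters
    ----------
    data : ndarray, shape (n_scans, n_regions)
        Regional BOLD samples (arbitrary units); must be finite.
    tr : float
        Sampling interval in seconds (> 0).
    region_names : list of str
        Unique, non-empty column labels; column order defines node index.
    """

    data: np.ndarray
    tr: float
    region_names: list[str]
    session_id: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (scans x regions)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if len(self.region_names) != self.data.shape[1]:
            raise ValueError("region_names length does not match data columns")
        if len(set(self.region_names)) != len(self.region_names):
            raise DuplicateRegionError("duplicate region name")
        if any(not name for name in self.region_names):
            raise ValueError("region names must be non-empty")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def demeaned(self) -> "RegionalTimeSeries":
        """Return a copy with each region's mean removed."""
        return RegionalTimeSeries(
            self.data - self.data.mean(axis=0, keepdims=True),
            self.tr,
            list(self.region_names),
            self.session_id,
            self.subject_id,
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(self.data, columns=self.region_names).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class WindowingScheme:
    """Rectangular sliding-window scheme given in scans.

    ``n_windows(n)`` is the closed form
    ``floor((n - window_length) / (window_length - overlap)) + 1``.
    """

    window_length: int
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if not (0 <= self.overlap < self.window_length):
            raise ValueError("overlap must satisfy 0 <= overlap < window_length")

    @property
    def step(self) -> int:
        return self.window_length - self.overlap

    def n_windows(self, n_scans: int) -> int:
        if n_scans < self.window_length:
            raise WindowExceedsSeriesError("window exceeds series")
        return (n_scans - self.window_length) // self.step + 1


@dataclass
class ConnectivityMatrix:
    """Square matrix of directed coupling strengths (Hz).

    ``convention`` distinguishes raw rate matrices (used by the
    simulator; stability means all eigenvalues have negative real part)
    from the estimation convention in which the diagonal holds the
    log-scaling of a fixed -0.5 Hz self-connection.
    """

    values: np.ndarray
    convention: str = "rate"
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connectivity matrix must be finite")
        if self.convention not in ("rate", "log_scaled_diagonal"):
            raise ValueError("unknown convention")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def effective_rate(self) -> np.ndarray:
        """Matrix in raw-rate convention (diagonal mapped through -0.5 exp)."""
        if self.convention == "rate":
            return self.values.copy()
        out = self.values.copy()
        np.fill_diagonal(out, -0.5 * np.exp(np.diag(self.values)))
        return out

    def is_stable(self) -> bool:
        return bool(np.all(np.linalg.eigvals(self.effective_rate()).real < 0))

    def to_log_scaled(self) -> "ConnectivityMatrix":
        """Convert a rate matrix to the estimation convention.

        Off-diagonals are unchanged; diagonal entries a_ii (< 0) become
        ln(-a_ii / 0.5).
        """
        if self.convention == "log_scaled_diagonal":
            return ConnectivityMatrix(self.values.copy(), self.convention, self.region_names)
        d = np.diag(self.values)
        if np.any(d >= 0):
            raise ValueError("rate diagonal must be negative to convert")
        out = self.values.copy()
        np.fill_diagonal(out, np.log(-d / 0.5))
        return ConnectivityMatrix(out, "log_scaled_diagonal", self.region_names)


def load_timeseries(
    path: str | os.PathLike,
    tr: float,
    delimiter: str | None = None,
    session_id: str | None = None,
    subject_id: str | None = None,
) -> RegionalTimeSeries:
    """Read a delimited text file of regional BOLD samples.

    The first row holds region names; every following row holds one scan.
    Delimiter is inferred from the extension (TSV/CSV) unless given.
    """
    if not os.path.exists(path):
        raise MissingFileError(f"missing file: {path}")
    if delimiter is None:
        delimiter = "," if str(path).lower().endswith(".csv") else "\t"
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise EmptyTimeSeriesError("empty time series")
    header = [c.strip() for c in lines[0].split(delimiter)]
    if len(set(header)) != len(header):
        raise DuplicateRegionError("duplicate region")
    if len(lines) == 1:
        raise EmptyTimeSeriesError("empty time series")
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.split(delimiter)
        if len(cells) != len(header):
            raise RaggedRowsError(f"ragged row at line {i}")
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise NonNumericCellError(f"non-numeric cell at line {i}") from exc
    return RegionalTimeSeries(
        np.asarray(rows), tr, header, session_id=session_id, subject_id=subject_id
    )


def segment_windows(
    ts: RegionalTimeSeries, scheme: WindowingScheme
) -> list[RegionalTimeSeries]:
    """Cut a series into overlapping rectangular windows.

    Windows start at offsets 0, step, 2*step, ...; each has exactly
    ``window_length`` scans; trailing scans that do not fill a window
    are dropped.
    """
    W = scheme.n_windows(ts.n_scans)  # raises if window exceeds series
    out = []
    for i in range(W):
        start = i * scheme.step
        out.append(
            RegionalTimeSeries(
                ts.data[start : start + scheme.window_length].copy(),
                ts.tr,
                list(ts.region_names),
                session_id=ts.session_id,
                subject_id=ts.subject_id,
            )
        )
    return out


def cross_session_similarity(
    matrices: list[ConnectivityMatrix] | list[np.ndarray],
    include_diagonal: bool = True,
) -> float:
    """Mean Pearson correlation between vectorized matrices over all pairs.

    This is the stability score for baseline connectivity across
    sessions: vectorize each matrix (diagonal included by default),
    correlate every unordered pair, and average.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices")
    arrs = []
    for m in matrices:
        v = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
        if v.shape != (
            matrices[0].values.shape
            if isinstance(matrices[0], ConnectivityMatrix)
            else np.asarray(matrices[0]).shape
        ):
            raise ValueError("shape mismatch between matrices")
        if include_diagonal:
            arrs.append(v.ravel())
        else:
            n = v.shape[0]
            arrs.append(v[~np.eye(n, dtype=bool)])
    rs = [
        np.corrcoef(a, b)[0, 1]
        for a, b in itertools.combinations(arrs, 2)
    ]
    return float(np.mean(rs))


def save_matrices_tsv(path: str | os.PathLike, matrix: np.ndarray, names: list[str]) -> None:
    pd.DataFrame(matrix, index=names, columns=names).to_csv(path, sep="\t")


def save_json(path: str | os.PathLike, obj: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
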