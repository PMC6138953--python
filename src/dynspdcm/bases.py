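"""Second-level temporal basis sets (design matrices over windows).

Four kinds are supported: the simple average (constant column only), an
orthonormal DCT-II set, PCA of successive first-level connectivity
estimates, and a smoothness-penalised functional PCA.  The first column
is always the constant regressor, so the effect attached to it is the
baseline connectivity A0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RankDeficientError


@dataclass
class TemporalBasisSet:
    """Design matrix X1 (W x K) with its construction kind.

    For kind="dct" (and "average") the columns are mutually orthonormal.
    """

    matrix: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2:
            raise ValueError("design must be 2-D")
        first = self.matrix[:, 0]
        if first[0] <= 0 or np.ptp(first) > 1e-12:
            raise ValueError("first column must be constant and positive")

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[0]

    @property
    def K(self) -> int:
        return self.matrix.shape[1]

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.matrix, columns=[f"{self.kind}_{k}" for k in range(self.K)]
        )
        df.to_csv(path, sep="\t", index=False)


def dct_column(W: int, k: int) -> np.ndarray:
    """Unit-norm DCT-II vector cos(pi/W * (n + 1/2) * k), n = 0..W-1."""
    n = np.arange(W)
    v = np.cos(np.pi / W * (n + 0.5) * k)
    return v / np.linalg.norm(v)


def make_dct_basis(W: int, K: int) -> TemporalBasisSet:
    """Orthonormal DCT-II basis: constant column then K-1 cosine harmonics."""
    if not (1 <= K <= W):
        raise ValueError("require 1 <= K <= W")
    X = np.column_stack([dct_column(W, k) for k in range(K)])
    return TemporalBasisSet(X, "dct")


def make_average_basis(W: int) -> TemporalBasisSet:
    X = np.full((W, 1), 1.0 / np.sqrt(W))
    return TemporalBasisSet(X, "average")


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude element positive."""
    out = U.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _stack_and_center(first_level_means: list[np.ndarray]) -> np.ndarray:
    X = np.vstack([np.asarray(m, float).ravel() for m in first_level_means])
    return X - X.mean(axis=0, keepdims=True)


def make_pca_basis(first_level_means: list[np.ndarray], K: int) -> TemporalBasisSet:
    """PCA basis: constant column plus leading left singular vectors.

    The W x P matrix of vectorized first-level connectivity estimates is
    column-centered (the constant column already spans the mean) and
    decomposed by SVD; columns 1..K-1 are the left singular vectors in
    order of singular value, sign-fixed for determinism.
    """
    W = len(first_level_means)
    if K > W:
        raise ValueError("K cannot exceed the number of windows")
    Xc = _stack_and_center(first_level_means)
    U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(sv > max(sv[0], 1e-300) * 1e-10)) if sv.size else 0
    if K - 1 > rank:
        raise RankDeficientError("rank deficient")
    cols = [np.full(W, 1.0 / np.sqrt(W))]
    if K > 1:
        cols.append(_fix_signs(U[:, : K - 1]))
        X = np.column_stack(cols)
    else:
        X = cols[0][:, None]
    return TemporalBasisSet(X, "pca")


def _second_difference(W: int) -> np.ndarray:
    D = np.zeros((W - 2, W))
    for i in range(W - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D


def _gcv_lambda(u: np.ndarray, D: np.ndarray) -> float:
    """Generalized cross-validation for the roughness penalty weight.

    Scores candidate weights by smoothing the raw (PCA) score with
    S = (I + lam * D'D)^{-1} and minimising ||u - S u||^2 / (1 - tr(S)/W)^2.
    """
    W = u.size
    DtD = D.T @ D
    best, best_lam = np.inf, 0.0
    for lam in np.logspace(-2, 3, 11):
        S = np.linalg.inv(np.eye(W) + lam * DtD)
        resid = u - S @ u
        denom = (1.0 - np.trace(S) / W) ** 2
        score = float(resid @ resid) / max(denom, 1e-12)
        if score < best:
            best, best_lam = score, lam
    return best_lam


def make_fpca_basis(
    first_level_means: list[np.ndarray],
    K: int,
    smoothness: float | str = "auto",
) -> TemporalBasisSet:
    """Functional PCA basis with a second-difference roughness penalty.

    Sequential penalised rank-one decomposition: each unit-norm score u
    maximises ||X^T u||^2 - lam * ||D2 u||^2 subject to orthogonality to
    previous scores (generalized eigenproblem on the deflated data).
    With lam = 0 this reduces to plain PCA.  Supervision terms of the
    general model are not used — only the smoothness constraint.
    """
    W = len(first_level_means)
    if K > W:
        raise ValueError("K cannot exceed the number of windows")
    Xc = _stack_and_center(first_level_means)
    sv = np.linalg.svd(Xc, compute_uv=False)
    rank = int(np.sum(sv > max(sv[0], 1e-300) * 1e-10)) if sv.size else 0
    if K - 1 > rank:
        raise RankDeficientError("rank deficient")

    D = _second_difference(W)
    if smoothness == "auto":
        U0, _, _ = np.linalg.svd(Xc, full_matrices=False)
        smoothness = _gcv_lambda(U0[:, 0], D) if rank else 0.0
    lam = float(smoothness)
    if lam < 0:
        raise ValueError("smoothness weight must be >= 0")

    P = D.T @ D
    scores = []
    Xd = Xc.copy()
    for _ in range(K - 1):
        M = Xd @ Xd.T - lam * P
        if scores:
            # project out previous scores to enforce orthogonality
            Q = np.eye(W) - np.column_stack(scores) @ np.column_stack(scores).T
            M = Q @ M @ Q
        M = 0.5 * (M + M.T)
        w, V = np.linalg.eigh(M)
        u = V[:, -1]
        scores.append(u)
        Xd = Xd - np.outer(u, u @ Xd)
    cols = [np.full(W, 1.0 / np.sqrt(W))]
    if scores:
        cols.append(_fix_signs(np.column_stack(scores)))
        X = np.column_stack(cols)
    else:
        X = cols[0][:, None]
    return TemporalBasisSet(X, "fpca")
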