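"""Dynamic Component extraction: the H matrix, its eigen problem, varimax.

Given selected gene pairs, the H matrix stacks one row per pair: the
elementwise product of the two standardized gene rows,
``h_n = g_{i,n} g_{j,n}``.  Under a standard-normal latent factor Z,
the liquid-association score of a pair with respect to Z is (up to 1/N)
the dot product z . h, so latent factors governing many pairs are unit
vectors z maximizing ``sum_m (z . h_m)^2`` — exactly the top
eigenvectors of the N x N matrix H'H.  These are the Dynamic
Components (DCs).

The eigen problem is solved in sample space (N x N, with N at most a
few thousand) rather than on the M x N H matrix directly, since M can
reach 10^6 while N stays small.

A varimax rotation of the leading components within their span can be
applied to align each component with a distinct group of h vectors;
rotation preserves unit norms, mutual orthogonality, and the column
space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from dyncorr.io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["HMatrix", "DynamicComponents", "build_h", "extract_dcs", "varimax_rotate"]


@dataclass(frozen=True)
class HMatrix:
    """M pairs x N samples matrix of elementwise gene-pair products."""

    values: np.ndarray
    pair_index: np.ndarray  # (M, 2) int array of (i, j) source rows

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "pair_index",
                           np.asarray(self.pair_index, dtype=np.int64))
        if self.values.ndim != 2:
            raise ValueError("H must be 2-D")
        if self.pair_index.shape != (self.values.shape[0], 2):
            raise ValueError("pair_index must align with H rows")

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DynamicComponents:
    """Orthonormal sample-space factors with eigenvalues.

    ``scores`` is N x K with unit-norm, mutually orthogonal columns
    z_1..z_K; ``eigenvalues`` holds the corresponding values of the
    objective sum_m (z_k . h_m)^2 (nonincreasing when unrotated).
    ``all_eigenvalues`` keeps the full spectrum of H'H for scree
    inspection.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    rotated: bool = False
    rotation_matrix: np.ndarray | None = None
    all_eigenvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "eigenvalues",
                           np.asarray(self.eigenvalues, dtype=float))
        if self.scores.ndim != 2:
            raise ValueError("scores must be N x K")
        if self.eigenvalues.shape != (self.scores.shape[1],):
            raise ValueError("one eigenvalue per component required")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def build_h(X: ExpressionMatrix, pairs: np.ndarray) -> HMatrix:
    """Stack elementwise products of standardized gene pairs into H."""
    if not X.standardized:
        raise ValueError("build_h requires a standardized matrix")
    pairs = np.asarray(pairs, dtype=np.int64)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (M, 2) index array")
    p = X.n_genes
    if pairs.size and (pairs.min() < 0 or pairs.max() >= p):
        raise IndexError(f"pair index out of range for {p} genes")
    H = X.values[pairs[:, 0]] * X.values[pairs[:, 1]]
    return HMatrix(H, pairs)


def _fix_signs(Z: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|loading| entry in H Z is positive."""
    L = H @ Z
    idx = np.argmax(np.abs(L), axis=0)
    signs = np.sign(L[idx, np.arange(Z.shape[1])])
    signs[signs == 0] = 1.0
    return Z * signs


def extract_dcs(H: HMatrix, K: int = 10) -> DynamicComponents:
    """Top-K eigenvectors of H'H — the Dynamic Components.

    z_1 attains the global maximum of sum_m (z . h_m)^2 over unit
    vectors; each later z_k maximizes the same objective orthogonally
    to its predecessors.  Signs are fixed so the loading with largest
    absolute value is positive, making output deterministic.
    """
    if K < 1:
        raise ValueError("K must be positive")
    n = H.n_samples
    if K > n:
        raise ValueError(f"K={K} exceeds sample count N={n}")
    if not np.any(H.values):
        raise ValueError("H is identically zero")
    A = H.values.T @ H.values
    asym = np.abs(A - A.T).max()
    if asym > 1e-8 * max(1.0, np.abs(A).max()):
        logger.warning("H'H asymmetric beyond tolerance (%.3g); symmetrizing", asym)
    A = (A + A.T) / 2.0
    evals, evecs = scipy.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    Z = _fix_signs(evecs[:, order[:K]], H.values)
    return DynamicComponents(
        scores=Z,
        eigenvalues=evals[:K],
        rotated=False,
        rotation_matrix=np.eye(K),
        all_eigenvalues=evals,
    )


def _varimax(L: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Orthogonal rotation maximizing the varimax criterion of loadings L.

    Standard SVD-based iteration on raw (non-Kaiser-normalized)
    loadings.  Returns the K x K rotation matrix R; rotated loadings
    are ``L @ R``.
    """
    m, k = L.shape
    R = np.eye(k)
    last = 0.0
    for _ in range(max_iter):
        LR = L @ R
        B = L.T @ (LR ** 3 - LR @ np.diag((LR ** 2).sum(axis=0)) / m)
        U, s, Vt = np.linalg.svd(B)
        R = U @ Vt
        crit = s.sum()
        if crit <= last * (1 + tol):
            break
        last = crit
    return R


def varimax_criterion(L: np.ndarray) -> float:
    """Sum over factors of the variance of squared loadings."""
    sq = L ** 2
    return float(((sq - sq.mean(axis=0)) ** 2).mean(axis=0).sum())


def varimax_rotate(
    D: DynamicComponents, H: HMatrix, n_keep: int | None = None
) -> DynamicComponents:
    """Varimax-rotate the first `n_keep` components within their span.

    The M x n_keep loading matrix L = H Z is rotated by the orthogonal
    matrix maximizing the varimax criterion; scores are rotated by the
    same matrix, so unit norms and mutual orthogonality are preserved
    and the column space is unchanged.  With fewer than two factors the
    input is returned unchanged.
    """
    if n_keep is None:
        n_keep = D.n_components
    if n_keep > D.n_components:
        raise ValueError("n_keep exceeds number of components")
    if n_keep < 2:
        logger.info("varimax with <2 factors is a no-op")
        return D
    Z = D.scores[:, :n_keep]
    L = H.values @ Z
    R = _varimax(L)
    if varimax_criterion(L @ R) < varimax_criterion(L):
        # rotation never decreases the criterion; identity is a safe floor
        R = np.eye(n_keep)
    Zr = _fix_signs(Z @ R, H.values)
    scores = D.scores.copy()
    scores[:, :n_keep] = Zr
    # per-component objective after rotation (no longer sorted)
    eig = D.eigenvalues.copy()
    eig[:n_keep] = ((H.values @ Zr) ** 2).sum(axis=0)
    full_R = np.eye(D.n_components)
    full_R[:n_keep, :n_keep] = R
    return DynamicComponents(
        scores=scores,
        eigenvalues=eig,
        rotated=True,
        rotation_matrix=full_R,
        all_eigenvalues=D.all_eigenvalues,
    )
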