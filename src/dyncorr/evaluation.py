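"""Scoring latent-factor recovery against known truth.

The benchmark metric pairs found factors with true factors greedily —
repeatedly take the (true, found) column pair with the globally
largest absolute Spearman correlation among those still unmatched —
and reports the mean absolute correlation over the K matched pairs.
Methods are conventionally allowed to produce K + 2 factors, of which
K get matched.

Two reference points accompany the metric: a plain PCA baseline (the
standard comparator), and the "gene-surrogate" upper limit — for each
true factor, the best absolute correlation achievable by any single
gene in the matrix.  The latter bounds what triplet-screening methods
that use genes as proxies of the latent state could ever achieve; it
is an upper limit that actual screening may not attain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.stats import rankdata

from dyncorr.io import ExpressionMatrix

__all__ = [
    "RecoveryResult",
    "match_factors",
    "la_screening_upper_limit",
    "pca_baseline",
]


@dataclass(frozen=True)
class RecoveryResult:
    """Matched factor pairs and their absolute correlations."""

    pairing: tuple[tuple[int, int], ...]  # (true index, found index)
    per_factor_abs_cor: np.ndarray
    mean_abs_cor: float
    method_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_factor_abs_cor",
                           np.asarray(self.per_factor_abs_cor, dtype=float))


def _rank_transform(A: np.ndarray) -> np.ndarray:
    """Column-wise midrank transform (Spearman = Pearson on ranks)."""
    return np.apply_along_axis(rankdata, 0, A)


def _abs_cor_matrix(true_Z: np.ndarray, found: np.ndarray,
                    metric: str) -> np.ndarray:
    if metric == "spearman":
        true_Z, found = _rank_transform(true_Z), _rank_transform(found)
    elif metric != "pearson":
        raise ValueError("metric must be 'spearman' or 'pearson'")
    tc = true_Z - true_Z.mean(axis=0)
    fc = found - found.mean(axis=0)
    tn = np.linalg.norm(tc, axis=0)
    fn = np.linalg.norm(fc, axis=0)
    if np.any(tn == 0) or np.any(fn == 0):
        raise ValueError("constant factor column")
    return np.abs((tc / tn).T @ (fc / fn))


def match_factors(true_Z: np.ndarray, found: np.ndarray,
                  metric: str = "spearman",
                  optimal: bool = False) -> RecoveryResult:
    """Greedily pair found factors with true factors by |correlation|.

    `found` may have more columns than `true_Z` (the K + 2 rule);
    exactly K pairs are made.  With ``optimal=True`` the
    assignment-problem optimum (maximizing total |correlation|) is used
    instead of the greedy sequence, for sensitivity checks.
    """
    true_Z = np.asarray(true_Z, dtype=float)
    found = np.asarray(found, dtype=float)
    if true_Z.ndim != 2 or found.ndim != 2:
        raise ValueError("factor inputs must be 2-D (samples x factors)")
    K, Kp = true_Z.shape[1], found.shape[1]
    if Kp < K:
        raise ValueError(f"found {Kp} factors but need at least {K}")
    C = _abs_cor_matrix(true_Z, found, metric)
    pairing: list[tuple[int, int]] = []
    per = np.empty(K)
    if optimal:
        from scipy.optimize import linear_sum_assignment
        rows, cols = linear_sum_assignment(-C)
        for t, f in zip(rows, cols):
            pairing.append((int(t), int(f)))
            per[t] = C[t, f]
        pairing.sort()
    else:
        M = C.copy()
        for _ in range(K):
            t, f = np.unravel_index(np.argmax(M), M.shape)
            pairing.append((int(t), int(f)))
            per[t] = C[t, f]
            M[t, :] = -np.inf
            M[:, f] = -np.inf
        pairing.sort()
    return RecoveryResult(
        pairing=tuple(pairing),
        per_factor_abs_cor=per,
        mean_abs_cor=float(per.mean()),
    )


def la_screening_upper_limit(X: ExpressionMatrix, true_Z: np.ndarray,
                             metric: str = "spearman") -> RecoveryResult:
    """Best single-gene |correlation| with each true factor.

    One gene per factor, maximized over all genes — the ceiling for
    any method that uses genes as surrogates of the latent state; may
    not be attainable in actual computation.
    """
    true_Z = np.asarray(true_Z, dtype=float)
    C = _abs_cor_matrix(true_Z, X.values.T, metric)  # K x p
    best = C.argmax(axis=1)
    per = C[np.arange(true_Z.shape[1]), best]
    return RecoveryResult(
        pairing=tuple((int(k), int(g)) for k, g in enumerate(best)),
        per_factor_abs_cor=per,
        mean_abs_cor=float(per.mean()),
        method_label="LA screening (upper limit, may not be attainable)",
    )


def pca_baseline(X: ExpressionMatrix, n_factors: int) -> np.ndarray:
    """Top principal-component sample scores of a standardized matrix.

    Sample-space eigenvectors of X'X (unit norm, orthogonal), with the
    same deterministic sign convention as Dynamic Component extraction:
    the gene loading with largest absolute value is made positive.
    """
    if not X.standardized:
        raise ValueError("pca_baseline expects a standardized matrix")
    p, n = X.values.shape
    if n_factors > min(p, n):
        raise ValueError("n_factors exceeds matrix rank bound")
    A = X.values.T @ X.values
    A = (A + A.T) / 2.0
    evals, evecs = scipy.linalg.eigh(A)
    order = np.argsort(evals)[::-1][:n_factors]
    Z = evecs[:, order]
    L = X.values @ Z
    idx = np.argmax(np.abs(L), axis=0)
    signs = np.sign(L[idx, np.arange(n_factors)])
    signs[signs == 0] = 1.0
    return Z * signs
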