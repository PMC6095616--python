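"""Associating gene pairs with a Dynamic Component via gamma and lfdr.

For a component score vector z and a candidate pair (g_i, g_j) with
product vector h, the statistic ``gamma = z . h`` estimates (up to 1/N)
the liquid-association score of the pair with respect to z.  Over a
broad candidate pool — the top 20% of pairs by LAC score by default —
most pairs are unrelated to z, so by the central limit theorem their
gammas are approximately normal, while truly associated pairs land in
the tails.  The collection of gammas is therefore modeled as a
two-group mixture

    f(gamma) = pi0 * f0(gamma) + (1 - pi0) * f1(gamma)

and each pair receives a local false discovery rate,
``lfdr = pi0 * f0(gamma) / f(gamma)``: the posterior probability that
the pair is null (not associated with the component).

The lfdr engine follows the classic empirical-Bayes recipe: the
marginal density f is a Poisson-regression spline smooth of histogram
counts, and the null component (mean, scale, pi0) is estimated by
central matching — a quadratic fit to log f around its central mode.
The null is fit on gamma itself, not |gamma|, because the sign carries
the direction of the dynamic correlation; selection is two-tailed.
Because smoothing can leave small non-monotone wiggles in the tails,
the lfdr curve is post-processed with a running minimum outward from
the mode, so selection sets are nested in |gamma - mode|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.stats import norm

from dyncorr.io import ExpressionMatrix
from dyncorr.lac import PairScoreTable, select_top_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "GammaStats",
    "LfdrFit",
    "candidate_pool",
    "gamma_stats",
    "fit_lfdr",
    "select_pairs_for_dc",
]


@dataclass(frozen=True)
class GammaStats:
    """Per-pair dot products with one component score vector."""

    dc_index: int
    gamma: np.ndarray
    pair_index: np.ndarray  # (M, 2)
    pool_frac: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float))
        object.__setattr__(self, "pair_index",
                           np.asarray(self.pair_index, dtype=np.int64))
        if self.pair_index.shape != (self.gamma.size, 2):
            raise ValueError("pair_index must align with gamma")


@dataclass(frozen=True)
class LfdrFit:
    """Two-group mixture fit over gamma statistics.

    ``lfdr[m]`` is the posterior null probability of pair m;
    ``null_mean`` / ``null_sd`` are the empirical-null parameters on
    the robust-standardized gamma scale; ``pi0`` the estimated null
    proportion.
    """

    pi0: float
    null_mean: float
    null_sd: float
    lfdr: np.ndarray
    gamma: np.ndarray
    pair_index: np.ndarray
    threshold: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "lfdr", np.asarray(self.lfdr, dtype=float))
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float))
        object.__setattr__(self, "pair_index",
                           np.asarray(self.pair_index, dtype=np.int64))
        if not 0.0 < self.pi0 <= 1.0:
            raise ValueError("pi0 must be in (0, 1]")
        if np.any((self.lfdr < 0) | (self.lfdr > 1)):
            raise ValueError("lfdr values must lie in [0, 1]")


def candidate_pool(
    T: PairScoreTable, pool_frac: float = 0.20
) -> np.ndarray:
    """Top `pool_frac` of all pairs by LAC score (same tie rules as
    top-pair selection, no count cap)."""
    return select_top_pairs(T, top_frac=pool_frac, max_pairs=T.n_pairs)


def gamma_stats(
    X: ExpressionMatrix,
    pool: np.ndarray,
    z: np.ndarray,
    dc_index: int = 0,
    pool_frac: float = float("nan"),
    chunk_size: int = 200_000,
) -> GammaStats:
    """gamma_m = sum_n z_n g_{i,n} g_{j,n} for every pool pair.

    Computed blockwise: the weighted gene matrix (z * G) is formed once
    and each gamma is a single dot-product row sum, so the pool's full
    H matrix is never materialized.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size != X.n_samples:
        raise ValueError("z must be a length-N vector")
    if abs(np.linalg.norm(z) - 1.0) > 1e-6:
        raise ValueError("z must have unit norm")
    pool = np.asarray(pool, dtype=np.int64)
    G = X.values
    Gz = G * z  # p x N
    out = np.empty(pool.shape[0], dtype=float)
    for start in range(0, pool.shape[0], chunk_size):
        stop = min(start + chunk_size, pool.shape[0])
        blk = pool[start:stop]
        out[start:stop] = np.einsum(
            "mn,mn->m", Gz[blk[:, 0]], G[blk[:, 1]]
        )
    return GammaStats(dc_index=dc_index, gamma=out, pair_index=pool,
                      pool_frac=pool_frac)


def _bspline_basis(x: np.ndarray, df: int, degree: int = 3) -> np.ndarray:
    """B-spline design matrix with `df` columns over the range of x."""
    n_interior = df - degree - 1
    lo, hi = float(x.min()), float(x.max())
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1] if n_interior > 0 else []
    knots = np.concatenate([
        np.repeat(lo, degree + 1), interior, np.repeat(hi, degree + 1)
    ])
    return BSpline.design_matrix(x, knots, degree).toarray()


def fit_lfdr(
    g: GammaStats,
    n_bins: int = 120,
    df: int = 10,
    central_frac: float = 0.50,
    threshold: float = 0.01,
) -> LfdrFit:
    """Fit the two-group mixture and compute per-pair lfdr values.

    Gammas are first divided by a robust scale (half the central 50%
    interquartile-style spread, Gaussian-consistent) so the histogram
    binning is portable across sample sizes; lfdr is invariant to this
    affine change.  The marginal density comes from a Poisson GLM of
    bin counts on a B-spline basis; the empirical null from a quadratic
    fit to log f over the central `central_frac` mass of the data.
    """
    gamma = np.asarray(g.gamma, dtype=float)
    m = gamma.size
    if m < 1000:
        raise ValueError(f"pool too small for mixture estimation (M={m} < 1000)")
    if not np.all(np.isfinite(gamma)):
        raise ValueError("non-finite gamma values")
    med = np.median(gamma)
    scale = (np.quantile(gamma, 0.75) - np.quantile(gamma, 0.25)) / 1.349
    if scale <= 0 or np.ptp(gamma) == 0:
        raise ValueError("degenerate (near-constant) gamma distribution")
    x = (gamma - med) / scale

    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    mids = (edges[:-1] + edges[1:]) / 2.0
    width = edges[1] - edges[0]

    basis = _bspline_basis(mids, df=df)
    glm = sm.GLM(counts, basis, family=sm.families.Poisson())
    fitted = glm.fit().predict(basis)
    f_mid = np.maximum(fitted, 1e-12) / (m * width)  # density at bin mids

    # central matching: quadratic fit of log f over the central mass
    qlo = (1.0 - central_frac) / 2.0
    lo, hi = np.quantile(x, [qlo, 1.0 - qlo])
    central = (mids >= lo) & (mids <= hi) & (fitted > 0)
    if central.sum() < 5:
        raise ValueError("too few central bins for null estimation")
    xc = mids[central]
    logf = np.log(f_mid[central])
    c2, c1, c0 = np.polyfit(xc, logf, 2)
    if c2 >= 0:
        # log-density not concave in the center: fall back to moment null
        null_mean, null_sd = 0.0, 1.0
        logger.warning("central log-density not concave; using robust moment null")
    else:
        null_mean = -c1 / (2.0 * c2)
        null_sd = float(np.sqrt(-1.0 / (2.0 * c2)))
    peak_logf = c0 + c1 * null_mean + c2 * null_mean ** 2 if c2 < 0 else float(
        np.interp(null_mean, mids, np.log(f_mid)))
    pi0 = float(np.exp(peak_logf) * null_sd * np.sqrt(2.0 * np.pi))
    if pi0 > 1.0:
        logger.warning("pi0 estimate %.3f > 1; clipping to 1", pi0)
        pi0 = 1.0
    pi0 = max(pi0, 1e-8)

    f0_mid = norm.pdf(mids, loc=null_mean, scale=null_sd)
    lfdr_mid = np.minimum(1.0, pi0 * f0_mid / f_mid)

    # enforce monotone decay outward from the fitted mode
    mode_bin = int(np.argmin(np.abs(mids - null_mean)))
    lfdr_mid[mode_bin:] = np.minimum.accumulate(lfdr_mid[mode_bin:])
    lfdr_mid[: mode_bin + 1] = np.minimum.accumulate(
        lfdr_mid[: mode_bin + 1][::-1]
    )[::-1]

    lfdr = np.interp(x, mids, lfdr_mid)
    lfdr = np.clip(lfdr, 0.0, 1.0)
    return LfdrFit(
        pi0=pi0,
        null_mean=float(null_mean),
        null_sd=float(null_sd),
        lfdr=lfdr,
        gamma=gamma,
        pair_index=g.pair_index,
        threshold=threshold,
    )


def select_pairs_for_dc(fit: LfdrFit, fdr_cut: float = 0.01):
    """Pairs with lfdr <= cutoff, tagged with the sign of gamma.

    Returns ``(pairs, signs)``: an (k, 2) index array and a +1/-1 array
    giving the direction of the dynamic correlation.
    """
    keep = fit.lfdr <= fdr_cut
    pairs = fit.pair_index[keep]
    signs = np.where(fit.gamma[keep] >= 0, 1, -1).astype(np.int8)
    return pairs, signs
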