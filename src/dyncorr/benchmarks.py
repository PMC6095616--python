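"""Reproducible evaluation experiments for the whole pipeline.

Each function here reruns one study-style experiment from scratch —
LAC score calibration, eigen-objective optimality, end-to-end
latent-factor recovery, lfdr calibration, enrichment-count exactness —
using only the package's public operations plus independent brute-force
oracles.  They power both the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import scipy.linalg
from scipy.stats import binom

from dyncorr.io import ExpressionMatrix, standardize
from dyncorr.lac import lac_pair, lac_matrix, select_top_pairs
from dyncorr.core import HMatrix, build_h, extract_dcs
from dyncorr.association import GammaStats, gamma_stats, fit_lfdr
from dyncorr.enrichment import (
    GeneSetCollection, within_process_test, between_process_test,
)
from dyncorr.simulation import SimulationSpec, simulate_dataset
from dyncorr.evaluation import match_factors, pca_baseline

__all__ = [
    "lac_calibration",
    "lac_mixture_curve",
    "eigen_optimality",
    "recovery_benchmark",
    "lfdr_null_calibration",
    "lfdr_spike_calibration",
    "enrichment_exactness",
]


def _standardize_vec(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std(ddof=0)


def lac_calibration(
    n: int = 1000,
    reps: int = 1000,
    rhos: tuple[float, ...] = (0.0, 0.4, 0.8),
    seed: int = 0,
) -> dict[tuple[str, float], float]:
    """Mean LAC score for plainly correlated bivariate-normal pairs.

    Returns ``{(form, rho): mean zeta}`` over `reps` Monte-Carlo
    replicates at sample size `n`.  Under bivariate normality the
    squared form centers at zero for every rho; the absolute form
    centers at zero only for independent pairs and goes negative with
    correlation.
    """
    rng = np.random.default_rng(seed)
    sums = {(form, rho): 0.0 for form in ("squared", "absolute") for rho in rhos}
    for rho in rhos:
        for _ in range(reps):
            u = rng.standard_normal(n)
            v = rng.standard_normal(n)
            x = _standardize_vec(u)
            y = _standardize_vec(rho * u + math.sqrt(1.0 - rho * rho) * v)
            for form in ("squared", "absolute"):
                sums[(form, rho)] += lac_pair(x, y, form)
    return {k: v / reps for k, v in sums.items()}


def lac_mixture_curve(
    n: int = 1000,
    reps: int = 1000,
    rhos: tuple[float, ...] = (0.4, 0.6, 0.8),
    seed: int = 0,
) -> dict[tuple[str, float], float]:
    """Mean LAC under the dynamic-correlation mixture design.

    One third of the samples correlate at +rho, one third at -rho, one
    third are independent — the generative pattern a dynamically
    correlated pair produces.  Mean score should be positive and
    increase with rho for both forms.
    """
    rng = np.random.default_rng(seed)
    third = n // 3
    sums = {(form, rho): 0.0 for form in ("squared", "absolute") for rho in rhos}
    for rho in rhos:
        rvec = np.concatenate([
            np.full(third, rho), np.full(third, -rho), np.zeros(n - 2 * third)
        ])
        for _ in range(reps):
            u = rng.standard_normal(n)
            v = rng.standard_normal(n)
            x = _standardize_vec(u)
            y = _standardize_vec(rvec * u + np.sqrt(1.0 - rvec ** 2) * v)
            for form in ("squared", "absolute"):
                sums[(form, rho)] += lac_pair(x, y, form)
    return {k: v / reps for k, v in sums.items()}


def eigen_optimality(
    n_matrices: int = 50,
    n_random: int = 100_000,
    seed: int = 0,
) -> dict[str, float]:
    """Check z_1 attains the eigen objective's maximum.

    For each random H (M <= 100 rows, N <= 10 samples), compares
    sum_m (z_1 . h_m)^2 from component extraction with the best of
    `n_random` random unit directions, and compares the eigenvalues of
    H'H with an independent SVD of H.  Returns the fraction of
    matrices where z_1 wins (ties count as wins) and the maximum
    eigenvalue discrepancy.
    """
    rng = np.random.default_rng(seed)
    wins = 0
    max_disc = 0.0
    for _ in range(n_matrices):
        m = int(rng.integers(5, 101))
        n = int(rng.integers(3, 11))
        H = rng.standard_normal((m, n))
        dcs = extract_dcs(HMatrix(H, np.column_stack(
            [np.zeros(m, int), np.ones(m, int)])), K=min(n, 3))
        obj_z1 = float(((H @ dcs.scores[:, 0]) ** 2).sum())
        U = rng.standard_normal((n_random, n))
        U /= np.linalg.norm(U, axis=1, keepdims=True)
        best_random = float(((H @ U.T) ** 2).sum(axis=0).max())
        if obj_z1 >= best_random - 1e-9:
            wins += 1
        sv = np.linalg.svd(H, compute_uv=False)
        ev = np.zeros(n)
        ev[: sv.size] = sv ** 2
        disc = np.max(np.abs(np.sort(ev)[::-1] - dcs.all_eigenvalues))
        max_disc = max(max_disc, float(disc))
    return {
        "win_rate": wins / n_matrices,
        "max_eigenvalue_discrepancy": max_disc,
        "n_matrices": n_matrices,
        "n_random_directions": n_random,
    }


def recovery_benchmark(
    n_replicates: int = 5,
    n_modules: int = 3,
    genes_per_module: int = 100,
    n_samples: int = 500,
    noise_sd: float = 0.5,
    setup: str = "s1",
    marginal: str = "normal",
    top_frac: float = 0.025,
    seed: int = 0,
) -> dict[str, list[float]]:
    """End-to-end latent-factor recovery, DCA vs the PCA baseline.

    For each replicate dataset: standardize, score all pairs (absolute
    LAC), select the top fraction, extract K + 2 components from H'H,
    and greedily match against the true factors by absolute Spearman
    correlation.  Returns per-replicate mean absolute correlations for
    both methods.
    """
    ss = np.random.SeedSequence(seed)
    dca_scores: list[float] = []
    pca_scores: list[float] = []
    k_found = n_modules + 2
    for child in ss.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        spec = SimulationSpec(
            n_modules=n_modules, genes_per_module=genes_per_module,
            n_samples=n_samples, noise_sd=noise_sd, setup=setup,
            marginal=marginal, seed=rep_seed,
        )
        ds = simulate_dataset(spec)
        X = standardize(ds.X)
        table = lac_matrix(X)
        top = select_top_pairs(table, top_frac=top_frac)
        H = build_h(X, top)
        dcs = extract_dcs(H, K=min(k_found, X.n_samples))
        dca_scores.append(
            match_factors(ds.true_factors, dcs.scores).mean_abs_cor)
        pca = pca_baseline(X, min(k_found, X.n_samples))
        pca_scores.append(
            match_factors(ds.true_factors, pca).mean_abs_cor)
    return {"dca": dca_scores, "pca": pca_scores}


def lfdr_null_calibration(
    n_seeds: int = 10,
    n_genes: int = 200,
    n_samples: int = 500,
    seed: int = 0,
) -> dict[str, list[float]]:
    """lfdr behavior on genuinely null gamma pools.

    Each pool: all C(n_genes, 2) pairs of i.i.d. standard-normal genes
    scored against a random unit z independent of every gene (with
    n_genes = 200 that is 19,900 pairs).  Returns per-seed pi0
    estimates and the fraction of pairs called at lfdr <= 0.01.
    """
    ss = np.random.SeedSequence(seed)
    pi0s: list[float] = []
    fracs: list[float] = []
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        G = rng.standard_normal((n_genes, n_samples))
        X = standardize(ExpressionMatrix(
            G, tuple(f"g{i}" for i in range(n_genes)),
            tuple(f"s{j}" for j in range(n_samples))))
        z = rng.standard_normal(n_samples)
        z /= np.linalg.norm(z)
        pairs = np.array(list(itertools.combinations(range(n_genes), 2)))
        g = gamma_stats(X, pairs, z, pool_frac=1.0)
        fit = fit_lfdr(g)
        pi0s.append(fit.pi0)
        fracs.append(float((fit.lfdr <= 0.01).mean()))
    return {"pi0": pi0s, "frac_called_at_01": fracs}


def lfdr_spike_calibration(
    n_seeds: int = 10,
    m: int = 20_000,
    spike_frac: float = 0.05,
    shift_sd: float = 6.0,
    seed: int = 0,
) -> dict[str, list[float]]:
    """lfdr recall/leakage on a spiked mixture with known labels.

    ``spike_frac`` of the gammas are shifted by ``shift_sd`` standard
    deviations (half up, half down); the rest are standard normal.
    Returns per-seed recall of spiked pairs and leakage of null pairs
    at lfdr <= 0.01.
    """
    ss = np.random.SeedSequence(seed)
    recalls: list[float] = []
    leaks: list[float] = []
    dummy_pairs = np.column_stack([np.arange(m), np.arange(m) + m])
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        labels = rng.random(m) < spike_frac
        gamma = rng.standard_normal(m)
        sign = np.where(rng.random(m) < 0.5, 1.0, -1.0)
        gamma[labels] += (sign * shift_sd)[labels]
        fit = fit_lfdr(GammaStats(0, gamma, dummy_pairs, 1.0))
        called = fit.lfdr <= 0.01
        recalls.append(float(called[labels].mean()))
        leaks.append(float(called[~labels].mean()))
    return {"recall": recalls, "leakage": leaks}


def _brute_force_enrichment(id_pairs, universe, sets):
    """Exhaustive-enumeration oracle for within/between counts and p."""
    U = len(universe)
    total = U * (U - 1) // 2
    n_sel = len(id_pairs)
    within = {}
    for name, members in sets.items():
        inside = sum(1 for a, b in id_pairs if a in members and b in members)
        s = len(members)
        n_inside_universe = sum(
            1 for a, b in itertools.combinations(sorted(universe), 2)
            if a in members and b in members
        )
        assert n_inside_universe == s * (s - 1) // 2
        prob = n_inside_universe / total
        within[name] = (
            inside, n_sel * prob,
            float(binom.sf(inside - 1, n_sel, prob)) if n_sel else 1.0,
        )
    between = {}
    names = sorted(sets)
    for x, y in itertools.combinations(names, 2):
        A1 = sets[x] - sets[y]
        B1 = sets[y] - sets[x]
        if not A1 or not B1:
            continue
        bridge = sum(
            1 for a, b in id_pairs
            if (a in A1 and b in B1) or (a in B1 and b in A1)
        )
        n_bridge_universe = sum(
            1 for a, b in itertools.combinations(sorted(universe), 2)
            if (a in A1 and b in B1) or (a in B1 and b in A1)
        )
        prob = n_bridge_universe / total
        between[(x, y)] = (
            bridge, n_sel * prob,
            float(binom.sf(bridge - 1, n_sel, prob)) if n_sel else 1.0,
        )
    return within, between


def enrichment_exactness(
    n_configs: int = 100,
    max_universe: int = 12,
    seed: int = 0,
) -> dict[str, float]:
    """Compare enrichment tests with exhaustive enumeration.

    Random toy configurations (universe size <= `max_universe`, 2-4
    gene sets, random selected pairs); reports the maximum absolute
    discrepancy in observed counts, expected counts and p-values.
    """
    rng = np.random.default_rng(seed)
    max_err = 0.0
    n_records = 0
    for _ in range(n_configs):
        U = int(rng.integers(5, max_universe + 1))
        genes = [f"g{i}" for i in range(U)]
        n_sets = int(rng.integers(2, 5))
        sets = {}
        for si in range(n_sets):
            size = int(rng.integers(2, U + 1))
            sets[f"P{si}"] = frozenset(rng.choice(genes, size=size, replace=False))
        all_pairs = list(itertools.combinations(range(U), 2))
        k = int(rng.integers(1, len(all_pairs) + 1))
        chosen = rng.choice(len(all_pairs), size=k, replace=False)
        pairs = np.array([all_pairs[c] for c in chosen])
        id_pairs = [(genes[i], genes[j]) for i, j in pairs]

        C = GeneSetCollection(sets=sets, universe=frozenset(genes))
        got_within = within_process_test(pairs, genes, C)
        got_between = between_process_test(pairs, genes, C)
        exp_within, exp_between = _brute_force_enrichment(
            id_pairs, frozenset(genes), sets)

        for e in got_within:
            obs, expd, p = exp_within[e.process_a]
            max_err = max(max_err, abs(e.observed - obs),
                          abs(e.expected - expd), abs(e.p_value - p))
            n_records += 1
        got_keys = set()
        for e in got_between:
            key = tuple(sorted((e.process_a, e.process_b)))
            got_keys.add(key)
            obs, expd, p = exp_between[key]
            max_err = max(max_err, abs(e.observed - obs),
                          abs(e.expected - expd), abs(e.p_value - p))
            n_records += 1
        assert got_keys == set(exp_between)
    return {"max_abs_error": max_err, "n_records": n_records,
            "n_configs": n_configs}
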