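"""Synthetic datasets with known latent dynamic-correlation structure.

Each dataset holds K modules.  A module is governed by one latent
factor z ~ N(0, 1) over the N samples; a pair of seed vectors (x, y)
is built sample-by-sample from a bivariate normal whose correlation
rho_z depends on z through one of three maps:

* ``s1``: rho = (Phi(z) - 0.5) * 2, Phi the standard normal CDF — a
  smooth monotone map of z onto (-1, 1).
* ``s2``: clamp z to [-3.2, 3.2], rho = sign(z) * |z / 3.2| — a weaker,
  near-linear relation.
* ``s3``: clamp, rho = sign(z) * |z / 3.2|**4 — extreme correlations
  are rare but low-correlation pairs are also rare.

Module genes are noisy copies of a randomly chosen seed vector pair;
noise genes are i.i.d. standard normal and as numerous as all module
genes together.  To mimic skewed, zero-inflated sequencing data, each
gene can be quantile-matched to a reference marginal: either a gene
drawn from a user-supplied reference matrix, or the built-in synthetic
zero-inflated log-normal generator (a stand-in reference constructed
here, with gene-specific zero fractions up to 0.75).

All randomness flows from the spec's single seed through independent
child streams (one per module, one for noise genes, one for marginal
matching), so regeneration is bit-for-bit reproducible and per-module
output does not depend on generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.stats import norm

from dyncorr.io import ExpressionMatrix

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "conditional_rho",
    "simulate_seed_pair",
    "simulate_dataset",
    "quantile_match",
    "synthetic_reference",
]

Setup = Literal["s1", "s2", "s3"]
_Z_CLAMP = 3.2


@dataclass(frozen=True)
class SimulationSpec:
    """Configuration for one synthetic dataset."""

    n_modules: int = 3
    genes_per_module: int = 100
    n_samples: int = 500
    n_seed_pairs: int = 10
    noise_sd: float = 0.5
    setup: Setup = "s1"
    marginal: Literal["normal", "matched"] = "normal"
    reference_matrix: ExpressionMatrix | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_modules, self.genes_per_module, self.n_samples,
               self.n_seed_pairs) < 1:
            raise ValueError("all counts must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.setup not in ("s1", "s2", "s3"):
            raise ValueError("setup must be one of s1, s2, s3")
        if self.marginal not in ("normal", "matched"):
            raise ValueError("marginal must be 'normal' or 'matched'")


@dataclass(frozen=True)
class SimulatedDataset:
    """A generated matrix plus the ground truth used to score recovery."""

    X: ExpressionMatrix
    true_factors: np.ndarray  # N x K
    module_of_gene: tuple[str, ...]  # per gene: "m<k>" or "noise"
    seed_pair_of_gene: tuple[int, ...]  # per gene: seed pair id, -1 for noise
    spec: SimulationSpec


def conditional_rho(z, setup: Setup = "s1"):
    """Conditional correlation rho_z = E(XY | z) for each setup.

    Vectorized over z; always inside [-1, 1].
    """
    z = np.asarray(z, dtype=float)
    if setup == "s1":
        rho = (norm.cdf(z) - 0.5) * 2.0
    elif setup == "s2":
        zc = np.clip(z, -_Z_CLAMP, _Z_CLAMP)
        rho = np.sign(zc) * np.abs(zc / _Z_CLAMP)
    elif setup == "s3":
        zc = np.clip(z, -_Z_CLAMP, _Z_CLAMP)
        rho = np.sign(zc) * np.abs(zc / _Z_CLAMP) ** 4
    else:
        raise ValueError(f"unknown setup {setup!r}")
    return rho if rho.ndim else float(rho)


def simulate_seed_pair(z_vec: np.ndarray, setup: Setup, rng: np.random.Generator):
    """Draw one seed pair (x, y) with sample-wise correlation rho(z_n).

    Each (x_n, y_n) comes from a bivariate normal with unit marginals
    and correlation ``conditional_rho(z_n)``; at |rho| = 1 the draw is
    exactly degenerate (y = ±x).
    """
    z_vec = np.asarray(z_vec, dtype=float)
    rho = np.asarray(conditional_rho(z_vec, setup))
    u = rng.standard_normal(z_vec.size)
    v = rng.standard_normal(z_vec.size)
    x = u
    y = rho * u + np.sqrt(np.maximum(0.0, 1.0 - rho ** 2)) * v
    return x, y


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Generate a full module + noise-gene dataset from a spec.

    Per module: one z vector, `n_seed_pairs` seed pairs, then module
    genes in pairs — pick a seed pair at random, add i.i.d.
    N(0, noise_sd^2) noise to both seeds to make two genes.  Noise
    genes (as many as all module genes) are i.i.d. standard normal.
    Genes are *not* re-standardized here; standardization belongs to
    preprocessing, as in the real pipeline.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_modules + 2)
    module_rngs = [np.random.default_rng(c) for c in children[:spec.n_modules]]
    noise_rng = np.random.default_rng(children[spec.n_modules])
    match_rng = np.random.default_rng(children[spec.n_modules + 1])

    N = spec.n_samples
    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    module_of: list[str] = []
    seed_pair_of: list[int] = []
    factors = np.empty((N, spec.n_modules))

    for k, rng in enumerate(module_rngs):
        z = rng.standard_normal(N)
        factors[:, k] = z
        seeds = [simulate_seed_pair(z, spec.setup, rng)
                 for _ in range(spec.n_seed_pairs)]
        g = 0
        while g < spec.genes_per_module:
            sp = int(rng.integers(spec.n_seed_pairs))
            sx, sy = seeds[sp]
            for base in (sx, sy):
                if g >= spec.genes_per_module:
                    break
                gene = base + rng.normal(0.0, spec.noise_sd, size=N)
                rows.append(gene)
                gene_ids.append(f"m{k}_g{g}")
                module_of.append(f"m{k}")
                seed_pair_of.append(sp)
                g += 1

    n_module_genes = len(rows)
    for q in range(n_module_genes):
        rows.append(noise_rng.standard_normal(N))
        gene_ids.append(f"noise_g{q}")
        module_of.append("noise")
        seed_pair_of.append(-1)

    values = np.vstack(rows)

    if spec.marginal == "matched":
        if spec.reference_matrix is not None:
            ref = spec.reference_matrix.values
            ridx = match_rng.integers(ref.shape[0], size=values.shape[0])
            refs = [ref[r] for r in ridx]
        else:
            refs = [synthetic_reference(N=max(N, 1000), rng=match_rng)
                    for _ in range(values.shape[0])]
        values = np.vstack([
            quantile_match(values[r], refs[r]) for r in range(values.shape[0])
        ])

    X = ExpressionMatrix(values, tuple(gene_ids),
                         tuple(f"s{n}" for n in range(N)), standardized=False)
    return SimulatedDataset(
        X=X,
        true_factors=factors,
        module_of_gene=tuple(module_of),
        seed_pair_of_gene=tuple(seed_pair_of),
        spec=spec,
    )


def synthetic_reference(N: int = 1000, rng: np.random.Generator | None = None,
                        max_zero_frac: float = 0.75) -> np.ndarray:
    """One synthetic zero-inflated, right-skewed reference marginal.

    A stand-in for a real sequencing-derived gene distribution: a
    log-normal body with a gene-specific point mass at zero (zero
    fraction uniform on [0, max_zero_frac]).
    """
    if rng is None:
        rng = np.random.default_rng()
    zero_frac = rng.uniform(0.0, max_zero_frac)
    mu = rng.normal(1.0, 1.0)
    sigma = rng.uniform(0.5, 1.5)
    body = rng.lognormal(mean=mu, sigma=sigma, size=N)
    zeros = rng.random(N) < zero_frac
    body[zeros] = 0.0
    return body


def quantile_match(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Give x the (interpolated) empirical distribution of `reference`.

    The output keeps the rank order of x and takes its values from the
    sorted reference, interpolated when lengths differ — the standard
    interpolating quantile normalization to a target marginal.
    """
    x = np.asarray(x, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if reference.size < 2:
        raise ValueError("reference must have length >= 2")
    if np.ptp(reference) == 0:
        raise ValueError("constant reference distribution")
    order = np.argsort(x, kind="stable")
    ref_sorted = np.sort(reference)
    probs_x = np.linspace(0.0, 1.0, x.size)
    probs_ref = np.linspace(0.0, 1.0, reference.size)
    out = np.empty_like(x)
    out[order] = np.interp(probs_x, probs_ref, ref_sorted)
    return out
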