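"""Synthetic dataset generation with known latent structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr, shapiro

from dyncorr.io import standardize
from dyncorr.lac import lac_pair
from dyncorr.simulation import (
    SimulationSpec,
    conditional_rho,
    simulate_seed_pair,
    simulate_dataset,
    quantile_match,
    synthetic_reference,
)


class TestConditionalRho:
    @pytest.mark.parametrize("setup", ["s1", "s2", "s3"])
    def test_zero_maps_to_zero(self, setup):
        assert conditional_rho(0.0, setup) == pytest.approx(0.0)

    def test_s2_truncation_endpoints(self):
        assert conditional_rho(3.2, "s2") == pytest.approx(1.0)
        assert conditional_rho(-3.2, "s2") == pytest.approx(-1.0)
        assert conditional_rho(10.0, "s2") == pytest.approx(1.0)

    def test_s3_quartic_value(self):
        assert conditional_rho(1.6, "s3") == pytest.approx(0.0625)

    def test_s1_uses_normal_cdf(self):
        from scipy.stats import norm
        z = 1.3
        assert conditional_rho(z, "s1") == pytest.approx(
            (norm.cdf(z) - 0.5) * 2)

    @given(z=st.floats(min_value=-50, max_value=50))
    @settings(max_examples=100, deadline=None)
    def test_bounded_in_unit_interval(self, z):
        for setup in ("s1", "s2", "s3"):
            assert -1.0 <= conditional_rho(z, setup) <= 1.0

    def test_odd_symmetry(self):
        z = np.linspace(-4, 4, 33)
        for setup in ("s1", "s2", "s3"):
            np.testing.assert_allclose(conditional_rho(-z, setup),
                                       -np.asarray(conditional_rho(z, setup)),
                                       atol=1e-12)


class TestSimulateSeedPair:
    def test_independent_when_rho_zero(self, rng):
        z = np.zeros(10000)
        x, y = simulate_seed_pair(z, "s1", rng)
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.05

    def test_degenerate_when_rho_one(self, rng):
        z = np.full(100, 3.2)
        x, y = simulate_seed_pair(z, "s2", rng)
        np.testing.assert_allclose(x, y, atol=1e-12)

    def test_liquid_association_sign(self, rng):
        """E(x y z) > 0 under setup s1: the generative design creates a
        positive three-way association."""
        positives = 0
        for _ in range(200):
            z = rng.standard_normal(1000)
            x, y = simulate_seed_pair(z, "s1", rng)
            if np.mean(x * y * z) > 0:
                positives += 1
        assert positives >= 190


class TestSimulateDataset:
    def test_noise_gene_count_equals_module_genes(self):
        ds = simulate_dataset(SimulationSpec(
            n_modules=1, genes_per_module=10, n_samples=50, seed=1))
        assert ds.X.n_genes == 20
        assert sum(m == "noise" for m in ds.module_of_gene) == 10

    def test_deterministic_given_seed(self):
        spec = SimulationSpec(n_modules=2, genes_per_module=6,
                              n_samples=40, seed=9)
        a = simulate_dataset(spec)
        b = simulate_dataset(spec)
        np.testing.assert_array_equal(a.X.values, b.X.values)
        np.testing.assert_array_equal(a.true_factors, b.true_factors)

    def test_zero_noise_limit_gives_seed_copies(self):
        spec = SimulationSpec(n_modules=1, genes_per_module=8, n_samples=60,
                              noise_sd=1e-12, seed=3)
        ds = simulate_dataset(spec)
        # genes sharing a seed pair come in (x, y) copies: successive
        # same-seed x-side genes are identical in the noiseless limit
        by_seed = {}
        for g, (mod, sp) in enumerate(zip(ds.module_of_gene,
                                          ds.seed_pair_of_gene)):
            if mod != "noise":
                by_seed.setdefault(sp, []).append(g)
        found_duplicate = False
        for genes in by_seed.values():
            rows = ds.X.values[genes]
            for a in range(len(genes)):
                for b in range(a + 1, len(genes)):
                    if np.allclose(rows[a], rows[b], atol=1e-9):
                        found_duplicate = True
        assert found_duplicate

    def test_normal_marginals_pass_shapiro(self):
        ds = simulate_dataset(SimulationSpec(
            n_modules=2, genes_per_module=20, n_samples=300, seed=5))
        module_rows = [g for g, m in enumerate(ds.module_of_gene)
                       if m != "noise"]
        pvals = [shapiro(ds.X.values[g]).pvalue for g in module_rows]
        assert np.mean(np.array(pvals) > 1e-4) >= 0.99

    def test_factors_nearly_independent(self):
        ds = simulate_dataset(SimulationSpec(
            n_modules=4, genes_per_module=5, n_samples=500, seed=11))
        C = np.corrcoef(ds.true_factors.T)
        off = np.abs(C[~np.eye(4, dtype=bool)])
        assert off.mean() < 0.1

    def test_dynamic_pairs_lac_exceeds_noise_pairs(self, rng):
        """Dynamic correlation structure exists: mean LAC over the
        truly dynamic pairs — opposite-side genes of the same seed
        pair — exceeds the mean over noise-noise pairs.  (Genes from
        different seed pairs are independent by construction and carry
        no signal.)"""
        wins = 0
        reps = 20
        for r in range(reps):
            ds = simulate_dataset(SimulationSpec(
                n_modules=1, genes_per_module=20, n_samples=500,
                noise_sd=0.5, seed=100 + r))
            X = standardize(ds.X)
            mod = [g for g, m in enumerate(ds.module_of_gene) if m != "noise"]
            noi = [g for g, m in enumerate(ds.module_of_gene) if m == "noise"]
            sp = ds.seed_pair_of_gene
            # genes alternate x-side / y-side within each draw
            within = [lac_pair(X.values[a], X.values[b])
                      for ai, a in enumerate(mod) for b in mod[ai + 1:]
                      if sp[a] == sp[b] and (a % 2) != (b % 2)]
            noise = [lac_pair(X.values[a], X.values[b])
                     for ai, a in enumerate(noi[:10]) for b in noi[ai + 1:10]]
            if np.mean(within) > np.mean(noise):
                wins += 1
        assert wins >= 17

    def test_matched_marginals_are_reference_like(self):
        ds = simulate_dataset(SimulationSpec(
            n_modules=1, genes_per_module=10, n_samples=200,
            marginal="matched", seed=21))
        # matched output is zero-inflated and nonnegative, unlike normals
        assert (ds.X.values >= 0).all()
        assert (ds.X.values == 0).any()

    def test_matched_mode_with_user_reference(self, rng):
        from dyncorr.io import ExpressionMatrix
        ref = ExpressionMatrix(
            np.abs(rng.standard_normal((5, 400))) ** 2,
            tuple(f"r{i}" for i in range(5)),
            tuple(f"s{j}" for j in range(400)))
        ds = simulate_dataset(SimulationSpec(
            n_modules=1, genes_per_module=4, n_samples=100,
            marginal="matched", reference_matrix=ref, seed=2))
        assert (ds.X.values >= 0).all()


class TestQuantileMatch:
    def test_identity_when_reference_is_self(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_allclose(quantile_match(x, x), x, atol=1e-12)

    def test_rank_order_preserved(self, rng):
        x = rng.standard_normal(200)
        ref = rng.lognormal(size=500)
        out = quantile_match(x, ref)
        assert spearmanr(x, out).statistic == pytest.approx(1.0)

    def test_small_x_sits_at_interpolated_quantiles(self, rng):
        x = rng.standard_normal(5)
        ref = np.sort(rng.standard_normal(1000))
        out = quantile_match(x, ref)
        # oracle: k-th smallest of x maps to reference quantile k/4
        expected = np.interp(np.linspace(0, 1, 5),
                             np.linspace(0, 1, 1000), ref)
        np.testing.assert_allclose(np.sort(out), expected, atol=1e-12)

    def test_constant_reference_errors(self, rng):
        with pytest.raises(ValueError, match="constant"):
            quantile_match(rng.standard_normal(10), np.ones(50))


def test_synthetic_reference_profile(rng):
    ref = synthetic_reference(N=2000, rng=rng)
    assert (ref >= 0).all()
    zero_frac = (ref == 0).mean()
    assert zero_frac <= 0.80
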