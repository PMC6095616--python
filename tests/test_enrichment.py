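"""Within/between gene-set enrichment against brute-force enumeration."""

import itertools

import numpy as np
import pytest
from scipy.stats import binom

from dyncorr.enrichment import (
    GeneSetCollection,
    EnrichmentEdge,
    load_gmt,
    within_process_test,
    between_process_test,
    filter_edges,
    edges_to_frame,
    export_graphml,
)
from dyncorr.benchmarks import enrichment_exactness


class TestLoadGmt:
    def test_size_filter_and_universe_intersection(self, tmp_path):
        universe = [f"g{i}" for i in range(200)]
        lines = [
            "big\tdesc\t" + "\t".join(universe[:150]),
            "small\tdesc\t" + "\t".join(universe[:3]),
            "mixed\tdesc\t" + "\t".join(universe[:80] + ["absent1", "absent2"]),
            "dup\tdesc\t" + "\t".join(universe[:60] + universe[:60]),
        ]
        path = tmp_path / "sets.gmt"
        path.write_text("\n".join(lines) + "\n")
        C = load_gmt(path, universe, min_size=50, max_size=1000)
        assert set(C.sets) == {"big", "mixed", "dup"}
        assert len(C.sets["mixed"]) == 80  # absent genes dropped
        assert len(C.sets["dup"]) == 60    # duplicates collapse

    def test_empty_after_filter_errors(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("only\tdesc\tg1\tg2\n")
        with pytest.raises(ValueError, match="no gene sets"):
            load_gmt(path, ["g1", "g2"], min_size=100, max_size=1000)


class TestWithinProcess:
    def test_saturated_process(self):
        genes = [f"g{i}" for i in range(6)]
        C = GeneSetCollection({"all": frozenset(genes)}, frozenset(genes))
        pairs = np.array([[0, 1], [2, 3], [4, 5], [1, 2]])
        (edge,) = within_process_test(pairs, genes, C)
        assert edge.observed == 4
        assert edge.expected == pytest.approx(4.0)
        assert edge.fold_change == pytest.approx(1.0)

    def test_toy_universe_matches_enumeration(self):
        genes = [f"g{i}" for i in range(6)]
        members = frozenset(genes[:3])
        C = GeneSetCollection({"P": members}, frozenset(genes))
        pairs = np.array([[0, 1], [0, 2], [3, 4], [0, 5]])
        (edge,) = within_process_test(pairs, genes, C)
        # oracle over all C(6,2)=15 pairs
        prob = sum(1 for a, b in itertools.combinations(genes, 2)
                   if a in members and b in members) / 15
        assert edge.observed == 2
        assert edge.expected == pytest.approx(4 * prob)
        assert edge.p_value == pytest.approx(binom.sf(1, 4, prob))

    def test_zero_observed_gives_p_one(self):
        genes = [f"g{i}" for i in range(5)]
        C = GeneSetCollection({"P": frozenset(genes[:2])}, frozenset(genes))
        (edge,) = within_process_test(np.array([[2, 3]]), genes, C)
        assert edge.observed == 0
        assert edge.p_value == pytest.approx(1.0)


class TestBetweenProcess:
    def test_minimal_disjoint_singletons(self):
        genes = [f"g{i}" for i in range(4)]
        C = GeneSetCollection(
            {"A": frozenset([genes[0]]), "B": frozenset([genes[1]])},
            frozenset(genes))
        (edge,) = between_process_test(np.array([[0, 1]]), genes, C)
        assert edge.observed == 1
        assert edge.expected == pytest.approx(1 / 6)  # C(4,2) = 6

    def test_identical_processes_skipped(self):
        genes = [f"g{i}" for i in range(5)]
        same = frozenset(genes[:3])
        C = GeneSetCollection({"A": same, "B": same}, frozenset(genes))
        assert between_process_test(np.array([[0, 1]]), genes, C) == []

    def test_overlap_removed_before_counting(self):
        genes = [f"g{i}" for i in range(8)]
        A = frozenset(genes[:4])        # g0..g3
        B = frozenset(genes[2:6])       # g2..g5; overlap g2, g3
        C = GeneSetCollection({"A": A, "B": B}, frozenset(genes))
        pairs = np.array([[0, 4], [2, 5], [1, 5], [0, 1]])
        (edge,) = between_process_test(pairs, genes, C)
        # bridging pairs after overlap removal: (g0,g4), (g1,g5); (g2,g5)
        # is excluded because g2 is in the overlap
        assert edge.observed == 2
        prob = 2 * 2 / (8 * 7 / 2)
        assert edge.expected == pytest.approx(4 * prob)


def test_exhaustive_oracle_sweep():
    """Counts, expectations and p-values match brute-force enumeration
    exactly on random small universes."""
    result = enrichment_exactness(n_configs=100, max_universe=12, seed=7)
    assert result["max_abs_error"] == 0.0
    assert result["n_records"] > 200


class TestFilterEdges:
    def _edges(self, rows):
        return [EnrichmentEdge(a, b, o, e, o / e, p) for a, b, o, e, p in rows]

    def test_identity_with_loose_cuts(self):
        edges = self._edges([("A", "B", 5, 1.0, 0.01), ("B", "C", 2, 1.0, 0.5)])
        kept, deg = filter_edges(edges, p_cut=1.0, fc_cut=0.0,
                                 min_connections=0)
        assert kept == edges
        assert deg["B"] == 2

    def test_matches_independent_filter(self, rng):
        names = [f"P{i}" for i in range(12)]
        rows = []
        for _ in range(300):
            a, b = rng.choice(names, 2, replace=False)
            o = int(rng.integers(0, 30))
            e = float(rng.uniform(0.5, 5.0))
            rows.append((a, b, o, e, float(rng.random())))
        edges = self._edges(rows)
        p_cut, fc_cut, min_conn = 0.3, 2.0, 3
        kept, deg = filter_edges(edges, p_cut, fc_cut, min_conn)
        # independent oracle
        stage1 = [e for e in edges
                  if e.p_value <= p_cut and e.fold_change >= fc_cut]
        count = {}
        for e in stage1:
            count[e.process_a] = count.get(e.process_a, 0) + 1
            count[e.process_b] = count.get(e.process_b, 0) + 1
        good = {n for n, c in count.items() if c >= min_conn}
        oracle = [e for e in stage1
                  if e.process_a in good and e.process_b in good]
        assert kept == oracle

    def test_null_pairs_rarely_enriched(self, rng):
        """Uniformly random selected pairs almost never clear the
        standard p/fold cuts on a synthetic 50-set collection."""
        genes = [f"g{i}" for i in range(60)]
        sets = {f"P{i}": frozenset(rng.choice(genes, 12, replace=False))
                for i in range(50)}
        C = GeneSetCollection(sets, frozenset(genes))
        flagged = total = 0
        for _ in range(20):
            all_pairs = np.array(
                list(itertools.combinations(range(60), 2)))
            sel = all_pairs[rng.choice(len(all_pairs), 120, replace=False)]
            edges = within_process_test(sel, genes, C)
            flagged += sum(1 for e in edges
                           if e.p_value <= 0.001 and e.fold_change >= 2)
            total += len(edges)
        assert flagged / total <= 0.005


def test_graphml_round_trip(tmp_path):
    import networkx as nx
    edges = [EnrichmentEdge("A", "B", 10, 2.0, 5.0, 1e-5),
             EnrichmentEdge("B", "C", 8, 1.0, 8.0, 1e-6)]
    _, deg = filter_edges(edges, 1.0, 0.0, 0)
    out = tmp_path / "net.graphml"
    export_graphml(edges, deg, out)
    G = nx.read_graphml(out)
    assert set(G.nodes) == {"A", "B", "C"}
    assert G["A"]["B"]["observed"] == 10


def test_bh_column_is_supplementary(rng):
    edges = [EnrichmentEdge("A", "A", 3, 1.0, 3.0, p)
             for p in rng.random(20)]
    df = edges_to_frame(edges)
    assert "bh_q" in df.columns
    assert (df["bh_q"] >= df["p_value"] - 1e-12).all()
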