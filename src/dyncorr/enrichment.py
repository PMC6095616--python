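"""Gene-set enrichment of dynamically correlated pairs.

Once pairs are associated with a Dynamic Component, the biology is
summarized at the level of gene sets (e.g. GO biological processes):

* within-process: for each set, count selected pairs with *both* genes
  in the set; compare with the expected count under random pair draws
  from the universe; one-sided binomial upper-tail p-value and fold
  change (observed / expected).
* between-process: for each pair of sets, remove their shared genes,
  count selected pairs bridging the two disjoint remainders, and test
  the same way.

The universe is the intersection of the analyzed matrix's genes with
the genes appearing in the collection; selected pairs are restricted
to it before counting.  The binomial model treats the n_sel selected
pairs as draws with replacement from the C(U, 2) universe pairs —
exactly the "randomly drawn pairs" null.  Edges surviving p-value and
fold-change cuts form a process-pair network exportable as GraphML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import binom

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentEdge",
    "load_gmt",
    "within_process_test",
    "between_process_test",
    "filter_edges",
    "edges_to_frame",
    "export_graphml",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets intersected with a gene universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty universe")
        for name, members in self.sets.items():
            if not members <= self.universe:
                raise ValueError(f"set {name!r} has genes outside the universe")


@dataclass(frozen=True)
class EnrichmentEdge:
    """One within- (a == b) or between-process enrichment record."""

    process_a: str
    process_b: str
    observed: int
    expected: float
    fold_change: float
    p_value: float


def load_gmt(
    path: str | Path,
    universe,
    min_size: int = 100,
    max_size: int = 1000,
) -> GeneSetCollection:
    """Load a GMT file, intersect with the universe, filter by size.

    GMT lines are tab-separated: set name, description, member genes.
    Sets are intersected with the universe first and then kept only if
    their surviving size lies in ``[min_size, max_size]``.
    """
    universe = frozenset(map(str, universe))
    sets: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            logger.warning("skipping malformed GMT line: %r", line[:60])
            continue
        name = parts[0]
        members = frozenset(parts[2:]) & universe
        if min_size <= len(members) <= max_size:
            sets[name] = members
    if not sets:
        raise ValueError(
            f"no gene sets of size [{min_size}, {max_size}] after "
            "intersecting with the universe"
        )
    return GeneSetCollection(sets=sets, universe=universe)


def _restrict_pairs(pairs, gene_ids, universe) -> list[tuple[str, str]]:
    """Map index pairs to id pairs and keep those fully inside the universe."""
    out = []
    for i, j in np.asarray(pairs, dtype=np.int64):
        a, b = gene_ids[i], gene_ids[j]
        if a in universe and b in universe:
            out.append((a, b))
    dropped = len(pairs) - len(out)
    if dropped:
        logger.info("enrichment: %d of %d selected pairs outside universe",
                    dropped, len(pairs))
    return out


def within_process_test(
    pairs, gene_ids, C: GeneSetCollection
) -> list[EnrichmentEdge]:
    """Within-process counts and binomial tests for every set.

    For a set of size s in a universe of U genes, with n_sel selected
    universe pairs, a random pair lands inside the set with probability
    C(s,2)/C(U,2); observed is compared with Binomial(n_sel, that)
    via the upper tail P(X >= observed).
    """
    id_pairs = _restrict_pairs(pairs, gene_ids, C.universe)
    n_sel = len(id_pairs)
    U = len(C.universe)
    total_pairs = U * (U - 1) / 2.0
    edges = []
    for name, members in C.sets.items():
        s = len(members)
        prob = (s * (s - 1) / 2.0) / total_pairs
        if prob <= 0:
            continue
        observed = sum(1 for a, b in id_pairs if a in members and b in members)
        expected = n_sel * prob
        fold = observed / expected if expected > 0 else float("nan")
        p = float(binom.sf(observed - 1, n_sel, prob)) if n_sel > 0 else 1.0
        edges.append(EnrichmentEdge(name, name, observed, expected, fold, p))
    return edges


def between_process_test(
    pairs, gene_ids, C: GeneSetCollection
) -> list[EnrichmentEdge]:
    """Between-process tests for every unordered pair of sets.

    Overlapping genes are removed from both sets first (A' = A - B,
    B' = B - A); a random pair bridges the remainders with probability
    |A'||B'|/C(U,2).  Set pairs whose remainder empties are skipped.
    """
    id_pairs = _restrict_pairs(pairs, gene_ids, C.universe)
    n_sel = len(id_pairs)
    U = len(C.universe)
    total_pairs = U * (U - 1) / 2.0
    names = sorted(C.sets)
    edges = []
    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            A, B = C.sets[names[ai]], C.sets[names[bi]]
            A1, B1 = A - B, B - A
            if not A1 or not B1:
                logger.info("skipping %s | %s: empty after overlap removal",
                            names[ai], names[bi])
                continue
            prob = len(A1) * len(B1) / total_pairs
            observed = sum(
                1 for a, b in id_pairs
                if (a in A1 and b in B1) or (a in B1 and b in A1)
            )
            expected = n_sel * prob
            fold = observed / expected if expected > 0 else float("nan")
            p = float(binom.sf(observed - 1, n_sel, prob)) if n_sel > 0 else 1.0
            edges.append(
                EnrichmentEdge(names[ai], names[bi], observed, expected, fold, p)
            )
    return edges


def filter_edges(
    edges: list[EnrichmentEdge],
    p_cut: float = 0.001,
    fc_cut: float = 4.0,
    min_connections: int = 50,
):
    """Threshold edges, then restrict to well-connected processes.

    Keeps edges with ``p <= p_cut`` and ``fold_change >= fc_cut``; then
    drops nodes (processes) with fewer than `min_connections` surviving
    edges, and the edges touching them.  Returns the kept edges and a
    node -> degree table for sizing nodes in a network view.
    """
    kept = [e for e in edges
            if e.p_value <= p_cut and np.isfinite(e.fold_change)
            and e.fold_change >= fc_cut]
    degree: dict[str, int] = {}
    for e in kept:
        degree[e.process_a] = degree.get(e.process_a, 0) + 1
        if e.process_b != e.process_a:
            degree[e.process_b] = degree.get(e.process_b, 0) + 1
    good = {n for n, d in degree.items() if d >= min_connections}
    final = [e for e in kept if e.process_a in good and e.process_b in good]
    degrees = pd.Series(degree, name="connections").sort_values(ascending=False)
    return final, degrees


def edges_to_frame(edges: list[EnrichmentEdge]) -> pd.DataFrame:
    """Tabulate edges; adds a Benjamini-Hochberg q column (supplementary,
    not used by the default raw-p filter)."""
    df = pd.DataFrame(
        [(e.process_a, e.process_b, e.observed, e.expected, e.fold_change,
          e.p_value) for e in edges],
        columns=["process_a", "process_b", "observed", "expected",
                 "fold_change", "p_value"],
    )
    if len(df):
        p = df["p_value"].to_numpy()
        order = np.argsort(p)
        q = np.empty_like(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        df["bh_q"] = np.clip(q, 0, 1)
    else:
        df["bh_q"] = []
    return df


def export_graphml(edges: list[EnrichmentEdge], degrees: pd.Series,
                   path: str | Path) -> None:
    """Write the process-pair network (node size = connection count)."""
    G = nx.Graph()
    for name, deg in degrees.items():
        G.add_node(name, connections=int(deg))
    for e in edges:
        if e.process_a == e.process_b:
            continue
        G.add_edge(e.process_a, e.process_b,
                   observed=int(e.observed), fold_change=float(e.fold_change),
                   p_value=float(e.p_value))
    nx.write_graphml(G, str(path))
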