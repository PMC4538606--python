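"""Seeded synthetic inputs with planted structure, plus brute-force oracles.

The bipartite generator draws independent background edges at a fixed
density for both layers (lncRNA-miRNA and miRNA-disease) and then, for
each planted (lncRNA, disease) pair, wires ``n_shared`` common miRNAs to
both endpoints on top of the background — so the planted pair shares at
least ``n_shared`` miRNAs by construction and should surface as the top
enrichment.  Planted pairs double as gold-standard positives.

Defaults mirror the study conditions used throughout the test suite:
a universe of 50 miRNAs, background density 0.05, and plants sharing
10 miRNAs.

The oracles are exhaustive-enumeration reference implementations used
only in tests; they refuse instances large enough to be slow.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .entities import AssociationSet, EntityId


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    seed: int = 0
    n_mirna: int = 50
    n_disease: int = 20
    n_lncrna: int = 30
    background_density: float = 0.05
    planted_pairs: tuple[tuple[int, int, int], ...] = ((0, 0, 10),)
    """(lncRNA index, disease index, n_shared) triples."""
    dag_depth: int = 3
    dag_branching: int = 2

    def __post_init__(self) -> None:
        if min(self.n_mirna, self.n_disease, self.n_lncrna) <= 0:
            raise ValueError("entity counts must be positive")
        if not 0 < self.background_density < 1:
            raise ValueError("background density must lie in (0, 1)")
        for l, d, k in self.planted_pairs:
            if k > self.n_mirna:
                raise ValueError(f"plant of {k} shared miRNAs exceeds n_mirna={self.n_mirna}")
            if not (0 <= l < self.n_lncrna and 0 <= d < self.n_disease):
                raise ValueError("planted pair indexes out of range")
        if self.dag_depth < 1 or self.dag_branching < 1:
            raise ValueError("dag_depth and dag_branching must be >= 1")


def _names(prefix: str, namespace: str, count: int) -> list[EntityId]:
    # No trailing "-<digit>": that pattern would be (wrongly) merged by the
    # miRNA genomic-copy rule when fixtures flow through the full pipeline.
    width = len(str(count))
    return [EntityId(namespace, f"{prefix}{i:0{width}d}") for i in range(count)]


def generate_bipartite_fixture(
    spec: FixtureSpec,
) -> tuple[AssociationSet, AssociationSet, AssociationSet]:
    """Generate (lnc_mir, mir_dis, gold) with planted shared-miRNA enrichment.

    Fully reproducible: one :class:`numpy.random.Generator` stream seeded
    from ``spec.seed`` drives every draw; no global random state.
    """
    rng = np.random.default_rng(spec.seed)
    mirnas = _names("mir", "mirna", spec.n_mirna)
    diseases = _names("disease", "disease", spec.n_disease)
    lncrnas = _names("lnc", "lncrna", spec.n_lncrna)

    lnc_mir = AssociationSet("lncrna", "mirna", provenance=f"fixture seed={spec.seed}")
    mir_dis = AssociationSet("mirna", "disease", provenance=f"fixture seed={spec.seed}")
    gold = AssociationSet("lncrna", "disease", provenance=f"fixture seed={spec.seed}")

    lm_mask = rng.random((spec.n_lncrna, spec.n_mirna)) < spec.background_density
    md_mask = rng.random((spec.n_mirna, spec.n_disease)) < spec.background_density
    for i, j in zip(*np.nonzero(lm_mask)):
        lnc_mir.add(lncrnas[i], mirnas[j])
    for i, j in zip(*np.nonzero(md_mask)):
        mir_dis.add(mirnas[i], diseases[j])

    # Plants only ever add edges, so the planted pair shares >= n_shared.
    for l_idx, d_idx, n_shared in spec.planted_pairs:
        shared = rng.choice(spec.n_mirna, size=n_shared, replace=False)
        for m_idx in shared:
            lnc_mir.add(lncrnas[l_idx], mirnas[m_idx])
            mir_dis.add(mirnas[m_idx], diseases[d_idx])
        gold.add(lncrnas[l_idx], diseases[d_idx])
    return lnc_mir, mir_dis, gold


def generate_dag_fixture(
    spec: FixtureSpec,
) -> tuple[dict[EntityId, set[EntityId]], nx.DiGraph]:
    """Random rooted term DAG plus a disease→leaf mapping.

    Terms are arranged in levels (a complete ``dag_branching``-ary tree of
    ``dag_depth`` levels below the root); every non-root term gets one
    tree parent, and extra parents from higher levels are added at random,
    keeping the graph acyclic by construction.  Each disease maps to one
    uniformly chosen leaf.
    """
    rng = np.random.default_rng(spec.seed)
    dag = nx.DiGraph()
    root = EntityId("mesh_term", "term_root")
    dag.add_node(root)
    levels: list[list[EntityId]] = [[root]]
    counter = 0
    for depth in range(1, spec.dag_depth + 1):
        level: list[EntityId] = []
        for parent in levels[-1]:
            for _ in range(spec.dag_branching):
                term = EntityId("mesh_term", f"term{counter:04d}")
                counter += 1
                dag.add_edge(parent, term)
                # Occasionally give the term a second parent from the same
                # upper level, making it a genuine DAG rather than a tree.
                if len(levels[-1]) > 1 and rng.random() < 0.2:
                    other = levels[-1][rng.integers(len(levels[-1]))]
                    if other != parent:
                        dag.add_edge(other, term)
                level.append(term)
        levels.append(level)

    leaves = levels[-1]
    diseases = _names("disease", "disease", spec.n_disease)
    mapping = {d: {leaves[rng.integers(len(leaves))]} for d in diseases}
    return mapping, dag


# ---------------------------------------------------------------------------
# Brute-force oracles (tests only)
# ---------------------------------------------------------------------------

def enumerate_overlap_counts(n: int, m: int, l: int) -> Counter:
    """Histogram of |draw ∩ successes| over all C(n, l) draws.

    The first ``m`` of ``n`` items are the successes; every l-subset is
    enumerated.  Limited to n <= 12.
    """
    if n > 12:
        raise ValueError("enumeration oracle limited to n <= 12")
    successes = set(range(m))
    counts: Counter = Counter()
    for draw in combinations(range(n), l):
        counts[len(successes.intersection(draw))] += 1
    return counts


def brute_force_hypergeom(n: int, m: int, l: int, x: int) -> float:
    """P(X >= x) by exhaustive enumeration over all draws (n <= 12)."""
    counts = enumerate_overlap_counts(n, m, l)
    total = sum(counts.values())
    return sum(c for k, c in counts.items() if k >= x) / total


def brute_force_bma(
    group_u: Sequence[EntityId],
    group_v: Sequence[EntityId],
    base: Mapping[tuple[EntityId, EntityId], float],
) -> float:
    """Best-match-average by explicit double loop (groups of <= 6)."""
    if not group_u or not group_v:
        raise ValueError("empty group")
    if len(group_u) > 6 or len(group_v) > 6:
        raise ValueError("brute-force BMA limited to groups of <= 6")

    def sim(a: EntityId, b: EntityId) -> float:
        if a == b:
            return 1.0
        return base.get((a, b), base.get((b, a), 0.0))

    total = 0.0
    for a in group_u:
        total += max(sim(a, b) for b in group_v)
    for b in group_v:
        total += max(sim(b, a) for a in group_u)
    return total / (len(group_u) + len(group_v))


def brute_force_auc(
    test_scores: Iterable[float], candidate_scores: Iterable[float]
) -> float:
    """AUC by counting concordant (test, candidate) pairs, ties at half.

    Lower score = stronger prediction.  Limited to lists of <= 50.
    """
    tests = list(test_scores)
    cands = list(candidate_scores)
    if not tests or not cands:
        raise ValueError("need at least one test and one candidate score")
    if len(tests) > 50 or len(cands) > 50:
        raise ValueError("brute-force AUC limited to lists of <= 50")
    concordant = 0.0
    for t in tests:
        for c in cands:
            if t < c:
                concordant += 1.0
            elif t == c:
                concordant += 0.5
    return concordant / (len(tests) * len(cands))
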