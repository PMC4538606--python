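r"""Disease semantic similarity from MeSH descriptor DAGs.

A disease is located in the MeSH hierarchy by one or more descriptor
terms.  Its DAG consists of those terms plus all their ancestors, with a
semantic contribution per node that decays moving up the hierarchy:

.. math::

    D(t) = \begin{cases} 1 & t \text{ is one of the disease's own terms} \\
    \Delta \cdot \max\{D(c) : c \text{ child of } t \text{ in the DAG}\}
    & \text{otherwise,} \end{cases}

with decay factor :math:`\Delta \in (0, 1)` (default 0.5, the customary
value for this family of methods).  The semantic value
:math:`DV = \sum_t D(t)` sums the contributions, and two diseases are
similar in proportion to the contribution mass on the DAG nodes they
share:

.. math::

    S_1(A, B) = \frac{\sum_{t \in T_A \cap T_B} (D_A(t) + D_B(t))}
                     {DV_A + DV_B} \in [0, 1].

Diseases occupying several MeSH tree positions get one merged DAG; a
node reachable from more than one position keeps the maximum
contribution, so contributions stay in (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .entities import EntityId

logger = logging.getLogger(__name__)

DEFAULT_DELTA = 0.5


@dataclass
class DiseaseDAG:
    """A disease's rooted ancestor graph with per-node contributions."""

    disease: EntityId
    nodes: frozenset[EntityId]
    contribution: dict[EntityId, float]
    semantic_value: float


@dataclass
class SimilarityMatrix:
    """Symmetric entity × entity similarity with unit diagonal."""

    entities: list[EntityId]
    values: np.ndarray

    def __post_init__(self) -> None:
        self._index = {e: i for i, e in enumerate(self.entities)}

    def __contains__(self, entity: EntityId) -> bool:
        return entity in self._index

    def value(self, a: EntityId, b: EntityId) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, rows: Sequence[EntityId], cols: Sequence[EntityId]) -> np.ndarray:
        r = [self._index[e] for e in rows]
        c = [self._index[e] for e in cols]
        return self.values[np.ix_(r, c)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame (entity_a, entity_b, value), upper triangle incl. diagonal."""
        rows = []
        for i, a in enumerate(self.entities):
            for j in range(i, len(self.entities)):
                rows.append((a.label, self.entities[j].label, float(self.values[i, j])))
        return pd.DataFrame(rows, columns=["entity_a", "entity_b", "value"])


def build_disease_dag(
    disease: EntityId,
    mapping: Mapping[EntityId, set[EntityId]],
    term_graph: nx.DiGraph,
    delta: float = DEFAULT_DELTA,
) -> DiseaseDAG:
    """Build one disease's DAG and contribution map.

    ``term_graph`` holds parent → child edges over MeSH terms; the DAG is
    the closure of the disease's own terms over their ancestors.
    """
    if not 0 < delta < 1:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    own = set(mapping.get(disease, ()))
    if not own:
        raise ValueError(f"disease {disease.label!r} has no MeSH term mapping")
    if not nx.is_directed_acyclic_graph(term_graph):
        raise ValueError("term graph is not acyclic")

    nodes = set(own)
    for term in own:
        if term in term_graph:
            nodes |= nx.ancestors(term_graph, term)

    # Children before parents: contributions propagate upward.
    sub = term_graph.subgraph(n for n in nodes if n in term_graph)
    order = list(nx.topological_sort(sub)) if sub.number_of_nodes() else []
    contribution: dict[EntityId, float] = {}
    for node in list(reversed(order)) + [t for t in own if t not in sub]:
        if node in contribution:
            continue
        if node in own:
            contribution[node] = 1.0
            continue
        children = [c for c in term_graph.successors(node) if c in nodes]
        contribution[node] = delta * max(contribution[c] for c in children)
    return DiseaseDAG(
        disease=disease,
        nodes=frozenset(nodes),
        contribution=contribution,
        semantic_value=float(sum(contribution.values())),
    )


def semantic_similarity(dag_a: DiseaseDAG, dag_b: DiseaseDAG) -> float:
    """Shared-contribution similarity between two disease DAGs, in [0, 1]."""
    shared = dag_a.nodes & dag_b.nodes
    if not shared:
        return 0.0
    overlap = sum(dag_a.contribution[t] + dag_b.contribution[t] for t in shared)
    return overlap / (dag_a.semantic_value + dag_b.semantic_value)


def semantic_similarity_matrix(
    diseases: Sequence[EntityId],
    mapping: Mapping[EntityId, set[EntityId]],
    term_graph: nx.DiGraph,
    delta: float = DEFAULT_DELTA,
) -> SimilarityMatrix:
    """Full pairwise disease similarity (the S1 matrix).

    Diseases without a MeSH mapping are excluded (logged) rather than
    given zero rows, so downstream group similarities are not deflated.
    """
    mapped = [d for d in diseases if mapping.get(d)]
    dropped = [d for d in diseases if not mapping.get(d)]
    if dropped:
        logger.warning(
            "excluding %d disease(s) without MeSH terms: %s",
            len(dropped),
            ", ".join(sorted(d.label for d in dropped)[:5]),
        )
    dags = [build_disease_dag(d, mapping, term_graph, delta) for d in mapped]
    n = len(dags)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = semantic_similarity(dags[i], dags[j])
    return SimilarityMatrix(entities=mapped, values=values)
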