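r"""Group-based functional similarity cascade (miRNA S2 and lncRNA FS).

Two cascaded applications of the best-match-average (BMA) scheme turn
disease semantic similarity into lncRNA functional similarity:

1. A miRNA ``u`` is annotated by its disease group ``D(u)``; the
   functional similarity of two miRNAs is the BMA of their disease groups
   over the disease semantic similarity matrix ``S1``:

   .. math::

       S_2(u, v) = \frac{\sum_{d \in D(u)} S(d, D(v))
                         + \sum_{d \in D(v)} S(d, D(u))}{|D(u)| + |D(v)|},

   where :math:`S(d, G) = \max_{g \in G} S_1(d, g)` is the element-group
   (best match) similarity.

2. A lncRNA ``i`` is annotated by its interacting miRNA group ``M(i)``;
   lncRNA functional similarity ``FS(i, j)`` applies the same BMA over
   ``S2``.

Annotations absent from the base matrix are dropped (logged) rather than
treated as zero-similarity, and entities whose groups become empty are
excluded from the output — the cascade is undefined for lncRNAs without
miRNA partners.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal, Mapping

import numpy as np

from .entities import AssociationSet, EntityId
from .semantics import SimilarityMatrix

logger = logging.getLogger(__name__)

Combiner = Literal["max", "mean"]


def element_group_similarity(
    element: EntityId,
    group: Iterable[EntityId],
    base: SimilarityMatrix,
    combiner: Combiner = "max",
) -> float:
    """Similarity of one element to a group: its best match (default) or mean."""
    group = list(group)
    if not group:
        raise ValueError("empty group")
    row = base.submatrix([element], group)[0]
    return float(row.max() if combiner == "max" else row.mean())


def group_group_similarity(
    group_u: Iterable[EntityId],
    group_v: Iterable[EntityId],
    base: SimilarityMatrix,
    combiner: Combiner = "max",
) -> float:
    """Best-match-average similarity between two annotation groups."""
    gu, gv = list(group_u), list(group_v)
    if not gu or not gv:
        raise ValueError("group similarity undefined for an empty group")
    cross = base.submatrix(gu, gv)
    if combiner == "max":
        forward = cross.max(axis=1).sum()
        backward = cross.max(axis=0).sum()
    else:
        forward = cross.mean(axis=1).sum()
        backward = cross.mean(axis=0).sum()
    return float((forward + backward) / (len(gu) + len(gv)))


def _filtered_groups(
    groups: Mapping[EntityId, frozenset[EntityId]],
    base: SimilarityMatrix,
    what: str,
) -> dict[EntityId, list[EntityId]]:
    """Drop annotations missing from the base matrix; log the counts."""
    kept: dict[EntityId, list[EntityId]] = {}
    dropped_annotations = 0
    dropped_entities = 0
    for entity, annots in groups.items():
        present = sorted(a for a in annots if a in base)
        dropped_annotations += len(annots) - len(present)
        if present:
            kept[entity] = present
        else:
            dropped_entities += 1
    if dropped_annotations:
        logger.warning(
            "%s: dropped %d annotation(s) absent from the base matrix", what, dropped_annotations
        )
    if dropped_entities:
        logger.warning(
            "%s: excluded %d entit(ies) left without annotations", what, dropped_entities
        )
    return kept


def _group_similarity_matrix(
    groups: dict[EntityId, list[EntityId]],
    base: SimilarityMatrix,
    combiner: Combiner,
) -> SimilarityMatrix:
    entities = sorted(groups)
    n = len(entities)
    values = np.eye(n)  # identical groups give 1; diagonal forced exact
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = group_group_similarity(
                groups[entities[i]], groups[entities[j]], base, combiner
            )
    return SimilarityMatrix(entities=entities, values=values)


def mirna_functional_similarity(
    mir_dis: AssociationSet,
    s1: SimilarityMatrix,
    combiner: Combiner = "max",
) -> SimilarityMatrix:
    """miRNA functional similarity (S2) from disease groups over S1."""
    if mir_dis.left_class == "mirna":
        groups = dict(mir_dis.left_groups())
    elif mir_dis.right_class == "mirna":
        groups = dict(mir_dis.right_groups())
    else:
        raise ValueError("mir_dis must have a mirna side")
    kept = _filtered_groups(groups, s1, "miRNA functional similarity")
    if not kept:
        raise ValueError("no miRNA has a disease annotation present in S1")
    return _group_similarity_matrix(kept, s1, combiner)


def lncrna_functional_similarity(
    lnc_mir: AssociationSet,
    s2: SimilarityMatrix,
    combiner: Combiner = "max",
) -> SimilarityMatrix:
    """lncRNA functional similarity (FS) from miRNA groups over S2."""
    if lnc_mir.left_class == "lncrna":
        groups = dict(lnc_mir.left_groups())
    elif lnc_mir.right_class == "lncrna":
        groups = dict(lnc_mir.right_groups())
    else:
        raise ValueError("lnc_mir must have a lncrna side")
    kept = _filtered_groups(groups, s2, "lncRNA functional similarity")
    if not kept:
        raise ValueError("no lncRNA has a miRNA annotation present in S2")
    return _group_similarity_matrix(kept, s2, combiner)
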