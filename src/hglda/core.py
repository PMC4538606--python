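r"""Hypergeometric scoring of lncRNA-disease pairs by shared miRNA partners.

The model tests, for every (lncRNA, disease) pair, whether the miRNAs
interacting with the lncRNA and the miRNAs associated with the disease
overlap more than chance expects.  With

* ``N`` — the total number of miRNAs associated with lncRNAs or diseases
  (the union of both miRNA sides),
* ``M`` — miRNAs interacting with the given lncRNA,
* ``L`` — miRNAs associated with the given disease,
* ``x`` — miRNAs shared by both,

the significance is the upper tail of the hypergeometric distribution

.. math::

    P = \sum_{k \ge x} \frac{\binom{M}{k}\binom{N-M}{L-k}}{\binom{N}{L}},

i.e. the probability of drawing at least ``x`` of the lncRNA's miRNAs when
``L`` miRNAs are sampled without replacement from the universe of ``N``.
P-values over all pairs are adjusted jointly by Benjamini-Hochberg FDR;
pairs with FDR below 0.05 are called candidate associations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import hypergeom

from .entities import AssociationSet, EntityId

Tail = Literal["ge", "gt"]


@dataclass(frozen=True)
class HypergeomParams:
    """Counts entering one pair's hypergeometric test."""

    N: int
    M: int
    L: int
    x: int

    def __post_init__(self) -> None:
        if min(self.N, self.M, self.L, self.x) < 0:
            raise ValueError(f"negative count in {self}")
        if self.M > self.N or self.L > self.N:
            raise ValueError(f"M and L must not exceed N in {self}")
        if self.x > min(self.M, self.L):
            raise ValueError(f"x exceeds min(M, L) in {self}")


@dataclass(frozen=True)
class PairScore:
    """One scored lncRNA-disease pair."""

    lncrna: EntityId
    disease: EntityId
    params: HypergeomParams
    pvalue: float
    fdr: float


def hypergeometric_tail_pvalue(params: HypergeomParams, tail: Tail = "ge") -> float:
    """Upper-tail hypergeometric probability for one pair.

    ``tail="ge"`` returns :math:`P(X \\ge x)` (the default enrichment
    convention; ``x = 0`` gives exactly 1); ``tail="gt"`` returns the
    strict tail :math:`P(X > x)`.  Evaluated through the survival function
    of :class:`scipy.stats.hypergeom`, which works in log-space and is
    stable for universes of at least :math:`10^4` miRNAs.
    """
    threshold = params.x - 1 if tail == "ge" else params.x
    return float(hypergeom.sf(threshold, params.N, params.M, params.L))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Implements the textbook step-up formula
    ``q(i) = min_{j >= i} m * p(j) / j`` on the sorted p-values, clipped
    to 1.  Sorting by raw and by adjusted p-values agree up to ties.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(adjusted, 0.0, 1.0, out=adjusted)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def score_all_pairs(
    lnc_mir: AssociationSet,
    mir_dis: AssociationSet,
    tail: Tail = "ge",
    lncrnas: Iterable[EntityId] | None = None,
    diseases: Iterable[EntityId] | None = None,
) -> list[PairScore]:
    """Score the full cross product of lncRNAs × diseases.

    The miRNA universe ``N`` is the union of miRNAs appearing in either
    association set.  By default the lncRNAs are those with at least one
    interaction in ``lnc_mir`` and the diseases those with at least one
    association in ``mir_dis``; explicit lists may extend either side, in
    which case entities without any miRNA partner get ``x = 0`` and
    p-value 1 rather than being dropped (the score matrix stays complete
    for downstream ranking).  FDR is adjusted jointly over all emitted
    p-values.
    """
    if "mirna" not in (lnc_mir.left_class, lnc_mir.right_class):
        raise ValueError("lnc_mir must have a mirna side")
    if "mirna" not in (mir_dis.left_class, mir_dis.right_class):
        raise ValueError("mir_dis must have a mirna side")

    lnc_groups = _groups_by_class(lnc_mir, "lncrna")
    dis_groups = _groups_by_class(mir_dis, "disease")
    for l in lncrnas or ():
        lnc_groups.setdefault(l, frozenset())
    for d in diseases or ():
        dis_groups.setdefault(d, frozenset())
    mir_universe = sorted(
        set().union(*lnc_groups.values(), *dis_groups.values(), set())
    )
    if not mir_universe:
        raise ValueError("empty miRNA universe: no miRNA appears in either set")
    mir_index = {m: i for i, m in enumerate(mir_universe)}
    n_universe = len(mir_universe)

    lncrnas = sorted(lnc_groups)
    diseases = sorted(dis_groups)
    # Binary incidence matrices over the shared miRNA index; the overlap
    # counts x for every pair come from one matrix product.
    A = np.zeros((len(lncrnas), n_universe), dtype=np.int32)
    for i, l in enumerate(lncrnas):
        A[i, [mir_index[m] for m in lnc_groups[l]]] = 1
    B = np.zeros((n_universe, len(diseases)), dtype=np.int32)
    for j, d in enumerate(diseases):
        B[[mir_index[m] for m in dis_groups[d]], j] = 1
    X = A @ B
    M = A.sum(axis=1)
    L = B.sum(axis=0)

    threshold = X - 1 if tail == "ge" else X
    pvals = hypergeom.sf(threshold, n_universe, M[:, None], L[None, :])
    np.clip(pvals, 0.0, 1.0, out=pvals)
    fdrs = bh_adjust(pvals.ravel()).reshape(pvals.shape)

    scores = []
    for i, l in enumerate(lncrnas):
        for j, d in enumerate(diseases):
            params = HypergeomParams(n_universe, int(M[i]), int(L[j]), int(X[i, j]))
            scores.append(PairScore(l, d, params, float(pvals[i, j]), float(fdrs[i, j])))
    return scores


def scores_to_frame(scores: Iterable[PairScore]):
    """Pair scores as a DataFrame (lncrna, disease, x, M, L, N, pvalue, fdr)."""
    import pandas as pd

    return pd.DataFrame(
        [
            (
                s.lncrna.label,
                s.disease.label,
                s.params.x,
                s.params.M,
                s.params.L,
                s.params.N,
                s.pvalue,
                s.fdr,
            )
            for s in scores
        ],
        columns=["lncrna", "disease", "x", "M", "L", "N", "pvalue", "fdr"],
    )


def read_scores(path) -> list[PairScore]:
    """Read a pair-score TSV written by :func:`scores_to_frame`."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    required = {"lncrna", "disease", "x", "M", "L", "N", "pvalue", "fdr"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        PairScore(
            EntityId("lncrna", row.lncrna),
            EntityId("disease", row.disease),
            HypergeomParams(int(row.N), int(row.M), int(row.L), int(row.x)),
            float(row.pvalue),
            float(row.fdr),
        )
        for row in frame.itertuples()
    ]


def _groups_by_class(assoc: AssociationSet, cls: str) -> dict[EntityId, frozenset[EntityId]]:
    """Neighbor sets keyed by the entities of class ``cls`` (miRNA side opposite)."""
    if assoc.left_class == cls:
        return dict(assoc.left_groups())
    if assoc.right_class == cls:
        return dict(assoc.right_groups())
    raise ValueError(f"association set has no {cls!r} side")


def significant_pairs(
    scores: Iterable[PairScore], fdr_threshold: float = 0.05
) -> list[PairScore]:
    """Pairs with FDR strictly below the threshold, best first."""
    kept = [s for s in scores if s.fdr < fdr_threshold]
    kept.sort(key=lambda s: (s.fdr, s.pvalue, s.lncrna.label, s.disease.label))
    return kept


def rank_for_disease(
    scores: Iterable[PairScore], disease: EntityId, lncrna: EntityId
) -> int:
    """1-based rank of a lncRNA in a disease's prediction list.

    The list is ordered by ascending p-value, ties broken by larger
    shared-miRNA count ``x``, then lexicographic lncRNA label, so the rank
    is deterministic.
    """
    rows = [s for s in scores if s.disease == disease]
    if not rows:
        raise ValueError(f"no scores for disease {disease}")
    rows.sort(key=lambda s: (s.pvalue, -s.params.x, s.lncrna.label))
    for position, s in enumerate(rows, start=1):
        if s.lncrna == lncrna:
            return position
    raise ValueError(f"pair ({lncrna}, {disease}) absent from scores")
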