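"""Leave-one-out cross validation, ROC curves and AUC over gold associations.

Each known (gold) lncRNA-disease association is left out in turn as the
test sample and ranked, by ascending p-value, against the candidate set:
all scored pairs without evidence of association (i.e. every scored pair
outside the gold set).  Sweeping the rank threshold yields TPR/FPR pairs,
hence a ROC curve; the AUC equals the Mann-Whitney concordance between
test and candidate scores, with ties counted one half.

Because the hypergeometric scorer uses no gold information, holding out
one association does not change any score, and the leave-one-out loop is
equivalent to ranking each positive once against the shared candidate
set.  That shortcut is the default; ``literal_folds=True`` runs the
explicit per-fold loop for parity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

from .core import PairScore
from .entities import AssociationSet, EntityId


@dataclass
class LoocvResult:
    """Outcome of the leave-one-out evaluation."""

    test_pairs: list[tuple[EntityId, EntityId]]
    test_scores: np.ndarray
    candidate_scores: np.ndarray
    ranks: np.ndarray  # 1-based; fractional when tied with candidates
    roc: np.ndarray  # (n_points, 2) array of (FPR, TPR)
    auc: float


def auc_from_ranks(ranks, n_candidates: int) -> float:
    """AUC from 1-based ranks of test pairs among ``n_candidates`` candidates.

    Equals the Mann-Whitney U statistic normalized by
    ``n_test * n_candidates``: a test pair at rank ``r`` beats
    ``n_candidates - (r - 1)`` candidates (fractional ranks encode ties at
    half weight).
    """
    ranks = np.asarray(ranks, dtype=float)
    if ranks.size == 0:
        raise ValueError("no ranks given")
    if n_candidates <= 0:
        raise ValueError("need at least one candidate")
    if np.any(ranks < 1) or np.any(ranks > n_candidates + 1):
        raise ValueError("ranks must lie in [1, n_candidates + 1]")
    return float(np.mean((n_candidates - ranks + 1.0) / n_candidates))


def _rank_against(test: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """1-based rank of each test score among candidates (lower score = better).

    Ties with candidate scores contribute half a position, the standard
    Mann-Whitney convention, so ranks may be half-integers.
    """
    sorted_c = np.sort(candidates)
    better = np.searchsorted(sorted_c, test, side="left")
    ties = np.searchsorted(sorted_c, test, side="right") - better
    return 1.0 + better + 0.5 * ties


def loocv(
    scores: list[PairScore],
    gold: AssociationSet,
    per_disease: bool = False,
    literal_folds: bool = False,
) -> LoocvResult:
    """Rank every gold association against the unverified candidate pairs.

    Parameters
    ----------
    scores
        Output of :func:`hglda.core.score_all_pairs`; must cover every
        gold pair.
    gold
        Known lncRNA-disease associations (the positives).
    per_disease
        Rank each test pair only among candidates sharing its disease
        instead of globally (sensitivity analysis); ranks are then
        normalized per candidate-list size before ROC/AUC pooling.
    literal_folds
        Run the explicit one-fold-per-positive loop instead of the
        equivalent rank-once shortcut.
    """
    score_map: dict[tuple[EntityId, EntityId], float] = {}
    for s in scores:
        key = (s.lncrna, s.disease) if s.lncrna.namespace == "lncrna" else (s.disease, s.lncrna)
        score_map[key] = s.pvalue

    gold_pairs = sorted(
        (l, d) if l.namespace == "lncrna" else (d, l) for l, d in gold.edges
    )
    missing = [p for p in gold_pairs if p not in score_map]
    if missing:
        listing = ", ".join(f"({l.label}, {d.label})" for l, d in missing[:10])
        raise ValueError(f"{len(missing)} gold pair(s) missing from scores: {listing}")

    gold_set = set(gold_pairs)
    candidate_keys = sorted(k for k in score_map if k not in gold_set)
    if not candidate_keys:
        raise ValueError("no candidate pairs left after removing gold associations")
    candidate_scores = np.array([score_map[k] for k in candidate_keys])
    test_scores = np.array([score_map[k] for k in gold_pairs])

    if per_disease:
        by_disease: dict[EntityId, list[float]] = {}
        for (_, d), v in zip(candidate_keys, candidate_scores):
            by_disease.setdefault(d, []).append(v)
        ranks = np.empty(len(gold_pairs))
        rel = np.empty(len(gold_pairs))  # normalized rank in [0, 1]
        for i, ((_, d), v) in enumerate(zip(gold_pairs, test_scores)):
            cands = np.array(by_disease.get(d, []))
            if cands.size == 0:
                raise ValueError(f"no candidate pairs for disease {d.label!r}")
            ranks[i] = _rank_against(np.array([v]), cands)[0]
            rel[i] = (ranks[i] - 1.0) / cands.size
        # Pool on the normalized-rank scale so candidate lists of
        # different sizes are comparable: FPR at normalized threshold t
        # is t itself, TPR the fraction of test pairs ranked within t.
        grid = np.linspace(0.0, 1.0, 101)
        tpr = np.array([(rel <= t).mean() for t in grid])
        roc = np.vstack([[0.0, 0.0], np.column_stack([grid, tpr]), [1.0, 1.0]])
        auc = float(np.mean(1.0 - rel))
        return LoocvResult(gold_pairs, test_scores, candidate_scores, ranks, roc, auc)

    if literal_folds:
        ranks = np.empty(len(gold_pairs))
        for i, v in enumerate(test_scores):
            ranks[i] = _rank_against(np.array([v]), candidate_scores)[0]
    else:
        ranks = _rank_against(test_scores, candidate_scores)

    auc = auc_from_ranks(ranks, len(candidate_scores))
    labels = np.r_[np.ones(test_scores.size), np.zeros(candidate_scores.size)]
    # Lower p-value = stronger prediction, so score by its negation.
    fpr, tpr, _ = roc_curve(labels, -np.r_[test_scores, candidate_scores])
    roc = np.column_stack([fpr, tpr])
    return LoocvResult(gold_pairs, test_scores, candidate_scores, ranks, roc, auc)
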