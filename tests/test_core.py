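"""Hypergeometric pair scoring, FDR adjustment, significance and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hglda import (
    AssociationSet,
    HypergeomParams,
    bh_adjust,
    hypergeometric_tail_pvalue,
    rank_for_disease,
    read_scores,
    score_all_pairs,
    scores_to_frame,
    significant_pairs,
)
from hglda.fixtures import brute_force_hypergeom

from conftest import disease, lncrna, mirna


@st.composite
def hypergeom_params(draw, max_n=40):
    n = draw(st.integers(1, max_n))
    m = draw(st.integers(0, n))
    l = draw(st.integers(0, n))
    x = draw(st.integers(0, min(m, l)))
    return HypergeomParams(n, m, l, x)


class TestHypergeometricTail:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (HypergeomParams(10, 4, 5, 0), 1.0),
            (HypergeomParams(10, 4, 5, 2), 186 / 252),
            (HypergeomParams(10, 4, 5, 4), 6 / 252),
        ],
    )
    def test_small_cases_match_enumeration(self, params, expected):
        assert hypergeometric_tail_pvalue(params) == pytest.approx(expected, abs=1e-12)
        assert brute_force_hypergeom(params.N, params.M, params.L, params.x) == pytest.approx(
            expected, abs=1e-15
        )

    def test_strict_tail_option(self):
        ge = hypergeometric_tail_pvalue(HypergeomParams(10, 4, 5, 2), tail="ge")
        gt = hypergeometric_tail_pvalue(HypergeomParams(10, 4, 5, 2), tail="gt")
        assert gt < ge
        assert gt == pytest.approx(
            brute_force_hypergeom(10, 4, 5, 3), abs=1e-12
        )

    @pytest.mark.parametrize(
        "bad", [(-1, 0, 0, 0), (5, 6, 2, 1), (5, 2, 6, 1), (5, 3, 3, 4)]
    )
    def test_invariant_violations_raise(self, bad):
        with pytest.raises(ValueError):
            HypergeomParams(*bad)

    @given(hypergeom_params())
    @settings(max_examples=200, deadline=None)
    def test_strictly_decreasing_in_x(self, params):
        """More shared miRNAs strictly shrinks the tail within the support.

        Below the support's lower bound max(0, M + L - N) the tail is
        pinned at exactly 1, so the strict decrease starts there.
        """
        if params.x >= min(params.M, params.L):
            return
        p_here = hypergeometric_tail_pvalue(params)
        p_next = hypergeometric_tail_pvalue(
            HypergeomParams(params.N, params.M, params.L, params.x + 1)
        )
        support_low = max(0, params.M + params.L - params.N)
        if params.x >= support_low:
            assert p_next < p_here
        else:
            assert p_here == p_next == 1.0

    @given(hypergeom_params())
    @settings(max_examples=200, deadline=None)
    def test_symmetric_in_m_and_l(self, params):
        """Swapping the lncRNA's and the disease's miRNA-set sizes changes nothing."""
        swapped = HypergeomParams(params.N, params.L, params.M, params.x)
        assert hypergeometric_tail_pvalue(params) == pytest.approx(
            hypergeometric_tail_pvalue(swapped), rel=1e-12, abs=1e-300
        )


def stepup_oracle(pvalues):
    """Textbook BH: q(i) = min_{j >= i} m p(j) / j on sorted values, in input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    best = float("inf")
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        best = min(best, pvalues[i] * m / (pos + 1))
        adjusted[i] = min(best, 1.0)
    return adjusted


class TestBhAdjust:
    @pytest.mark.parametrize(
        "pvalues, expected",
        [
            ([0.005], [0.005]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.03, 0.002], [0.03, 0.004]),
        ],
    )
    def test_hand_computed_stepup(self, pvalues, expected):
        assert bh_adjust(pvalues) == pytest.approx(expected, abs=1e-15)

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40)).tolist()
            assert bh_adjust(p).tolist() == pytest.approx(stepup_oracle(p), abs=0)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(6)
        p = rng.uniform(size=200)
        expected = statsmodels.multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    def test_order_preserving(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        assert np.all(np.diff(q[np.argsort(p, kind="stable")]) >= 0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestScoreAllPairs:
    def build(self):
        lnc_mir = AssociationSet(
            "lncrna",
            "mirna",
            [
                (lncrna("l1"), mirna("m1")),
                (lncrna("l1"), mirna("m2")),
                (lncrna("l2"), mirna("m3")),
            ],
        )
        mir_dis = AssociationSet(
            "mirna",
            "disease",
            [
                (mirna("m1"), disease("d1")),
                (mirna("m2"), disease("d1")),
                (mirna("m3"), disease("d2")),
                (mirna("m4"), disease("d3")),
            ],
        )
        return lnc_mir, mir_dis

    def test_cross_product_count_and_universe(self):
        lnc_mir, mir_dis = self.build()
        scores = score_all_pairs(lnc_mir, mir_dis)
        assert len(scores) == 2 * 3
        assert all(s.params.N == 4 for s in scores)

    def test_disjoint_pair_gets_pvalue_one(self):
        lnc_mir, mir_dis = self.build()
        scores = {(s.lncrna.label, s.disease.label): s for s in score_all_pairs(lnc_mir, mir_dis)}
        s = scores[("l1", "d2")]
        assert s.params.x == 0
        assert s.pvalue == 1.0

    def test_explicit_entities_without_partners_score_one(self):
        lnc_mir, mir_dis = self.build()
        scores = score_all_pairs(lnc_mir, mir_dis, lncrnas=[lncrna("l9")])
        assert len(scores) == 3 * 3
        orphan = [s for s in scores if s.lncrna.label == "l9"]
        assert all(s.pvalue == 1.0 and s.params.M == 0 for s in orphan)

    def test_fdr_never_below_pvalue(self):
        lnc_mir, mir_dis = self.build()
        for s in score_all_pairs(lnc_mir, mir_dis):
            assert s.fdr >= s.pvalue - 1e-15
            assert 0.0 < s.pvalue <= 1.0

    def test_planted_pair_attains_minimum_pvalue(self, planted_fixture):
        lnc_mir, mir_dis, _ = planted_fixture
        scores = score_all_pairs(lnc_mir, mir_dis)
        best = min(scores, key=lambda s: s.pvalue)
        assert (best.lncrna.label, best.disease.label) == ("lnc00", "disease00")

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError, match="empty miRNA universe"):
            score_all_pairs(
                AssociationSet("lncrna", "mirna"), AssociationSet("mirna", "disease")
            )

    def test_score_table_round_trip(self, tmp_path, planted_fixture):
        lnc_mir, mir_dis, _ = planted_fixture
        scores = score_all_pairs(lnc_mir, mir_dis)
        path = tmp_path / "scores.tsv"
        scores_to_frame(scores).to_csv(path, sep="\t", index=False)
        again = read_scores(path)
        assert [(s.lncrna, s.disease) for s in again] == [
            (s.lncrna, s.disease) for s in scores
        ]
        np.testing.assert_allclose(
            [s.pvalue for s in again], [s.pvalue for s in scores], rtol=1e-12
        )


class TestSignificantAndRanks:
    def test_strict_threshold(self):
        scores = _scores([("l1", "d", 3, 0.001, 0.01), ("l2", "d", 2, 0.01, 0.05),
                          ("l3", "d", 1, 0.1, 0.2)])
        assert [s.lncrna.label for s in significant_pairs(scores, 0.05)] == ["l1"]

    def test_empty_and_all_null(self):
        assert significant_pairs([]) == []
        scores = _scores([("l1", "d", 0, 1.0, 1.0), ("l2", "d", 0, 1.0, 1.0)])
        assert significant_pairs(scores) == []

    def test_rank_positions(self):
        scores = _scores(
            [("l1", "d", 3, 0.001, 0.1), ("l2", "d", 2, 0.3, 0.4), ("l3", "d", 1, 0.7, 0.8)]
        )
        assert rank_for_disease(scores, disease("d"), lncrna("l1")) == 1
        assert rank_for_disease(scores, disease("d"), lncrna("l3")) == 3

    def test_tie_broken_by_shared_count_then_label(self):
        scores = _scores(
            [("lb", "d", 5, 0.01, 0.1), ("la", "d", 2, 0.01, 0.1), ("lc", "d", 5, 0.01, 0.1)]
        )
        assert rank_for_disease(scores, disease("d"), lncrna("lb")) == 1
        assert rank_for_disease(scores, disease("d"), lncrna("lc")) == 2
        assert rank_for_disease(scores, disease("d"), lncrna("la")) == 3

    def test_absent_pair_raises(self):
        scores = _scores([("l1", "d", 1, 0.5, 0.5)])
        with pytest.raises(ValueError, match="absent"):
            rank_for_disease(scores, disease("d"), lncrna("l9"))
        with pytest.raises(ValueError, match="no scores"):
            rank_for_disease(scores, disease("other"), lncrna("l1"))


def _scores(rows):
    from hglda import HypergeomParams, PairScore

    out = []
    for l, d, x, p, fdr in rows:
        params = HypergeomParams(100, max(x, 10), max(x, 10), x)
        out.append(PairScore(lncrna(l), disease(d), params, p, fdr))
    return out
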