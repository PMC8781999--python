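"""Enrichment scores, scaffold filters, repurposing score and ROC thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2 as chi2_dist

from faahscreen.roc import rank_auc, threshold_at_sensitivity
from faahscreen.scaffolds import ScaffoldKey
from faahscreen.scoring import (
    EnrichmentContext,
    containment_chi2_p,
    evaluate_filter,
    exclusive_coverage,
    null_fraction,
    p_score,
    repurposing_score,
    rps_threshold,
    score_scaffolds,
    select_filter_scaffolds,
)

CTX = EnrichmentContext(n_fi=1244, n_dcy=12440)


def key(s, kind="PR"):
    return ScaffoldKey(kind=kind, canonical=s)


class TestPScore:
    def test_prior(self):
        assert CTX.prior == pytest.approx(0.090909, abs=1e-6)

    def test_absent_from_actives(self):
        assert p_score(0, 5, CTX.prior) == 0.0

    def test_exclusive_scaffold_hits_upper_bound(self):
        assert p_score(7, 0, CTX.prior) == pytest.approx(1.0 / CTX.prior)
        assert p_score(7, 0, CTX.prior) == pytest.approx(11.0, abs=1e-6)

    def test_null_skeleton_counts(self):
        # the skeleton shared by 48 actives and 57 decoys
        assert p_score(48, 57, CTX.prior) == pytest.approx(5.03, abs=0.005)

    @settings(max_examples=50, derandomize=True)
    @given(
        cf=st.integers(0, 100), cd=st.integers(0, 100), k=st.integers(2, 9)
    )
    def test_scale_invariance_and_bounds(self, cf, cd, k):
        if cf + cd == 0:
            return
        p = p_score(cf, cd, CTX.prior)
        assert 0.0 <= p <= 1.0 / CTX.prior + 1e-12
        assert p_score(k * cf, k * cd, CTX.prior) == pytest.approx(p)


class TestChiSquare:
    @pytest.mark.parametrize(
        "cf,cd", [(48, 57), (10, 100), (3, 0), (0, 12), (100, 1000)]
    )
    def test_matches_first_principles_pearson(self, cf, cd):
        # brute-force Pearson statistic on the 2x2 containment table
        observed = np.array([[cf, CTX.n_fi - cf], [cd, CTX.n_dcy - cd]], dtype=float)
        row = observed.sum(axis=1, keepdims=True)
        col = observed.sum(axis=0, keepdims=True)
        expected = row @ col / observed.sum()
        stat = ((observed - expected) ** 2 / expected).sum()
        p_oracle = float(chi2_dist.sf(stat, df=1))
        assert containment_chi2_p(cf, cd, CTX) == pytest.approx(p_oracle, rel=1e-10)

    def test_scaffold_in_every_compound_is_uninformative(self):
        ctx = EnrichmentContext(n_fi=10, n_dcy=100)
        assert containment_chi2_p(10, 100, ctx) == 1.0


class TestScoreScaffolds:
    def _assign(self, spec):
        return {cid: {key(s) for s in keys} for cid, keys in spec.items()}

    def test_counts_scores_and_ordering(self):
        ctx = EnrichmentContext(n_fi=3, n_dcy=6)
        fi = self._assign({"a": ["X", "Y"], "b": ["X"], "c": ["Y"]})
        dcy = self._assign({f"d{i}": ["Y"] for i in range(6)} | {"d0": ["Y", "Z"]})
        pic50 = {"a": 8.0, "b": 6.0, "c": 7.0}
        scores = score_scaffolds(fi, dcy, ctx, pic50)
        by_name = {s.key.canonical: s for s in scores}
        assert by_name["X"].count_fi == 2 and by_name["X"].count_dcy == 0
        assert by_name["X"].p_score == pytest.approx(1 / ctx.prior)
        assert by_name["X"].i_score == pytest.approx(7.0)  # mean of a, b
        assert by_name["Z"].p_score == 0.0 and by_name["Z"].i_score is None
        assert [s.key.canonical for s in scores] == sorted(
            by_name, key=lambda n: -by_name[n].p_score
        )

    def test_i_score_within_member_range(self, small_library):
        from faahscreen.scaffolds import assign_scaffolds

        _, fi, dcy, _ = small_library
        ctx = EnrichmentContext(len(fi), len(dcy))
        pic50 = {r.id: r.pic50 for r in fi}
        scores = score_scaffolds(
            assign_scaffolds(fi, "PR"), assign_scaffolds(dcy, "PR"), ctx, pic50
        )
        assert scores, "library must contain ring scaffolds"
        for s in scores:
            if s.i_score is not None:
                assert min(pic50.values()) <= s.i_score <= max(pic50.values())


class TestEvaluateFilter:
    def _sets(self, n_pos_hit, n_pos, n_neg_hit, n_neg):
        filt = {key("F")}
        fi = {f"p{i}": ({key("F")} if i < n_pos_hit else {key("O")}) for i in range(n_pos)}
        dcy = {f"n{i}": ({key("F")} if i < n_neg_hit else {key("O")}) for i in range(n_neg)}
        return filt, fi, dcy

    def test_definition_arithmetic(self):
        filt, fi, dcy = self._sets(60, 100, 10, 100)
        report = evaluate_filter(filt, fi, dcy)
        assert report.sensitivity == pytest.approx(0.6)
        assert report.specificity == pytest.approx(0.9)

    def test_filter_matching_everything(self):
        filt, fi, dcy = self._sets(100, 100, 100, 100)
        report = evaluate_filter(filt, fi, dcy)
        assert report.sensitivity == 1.0 and report.specificity == 0.0

    def test_empty_filter_degenerate(self):
        _, fi, dcy = self._sets(1, 10, 1, 10)
        report = evaluate_filter(set(), fi, dcy)
        assert report.sensitivity == 0.0 and report.specificity == 1.0

    def test_monotonicity_in_filter_size(self):
        fi = {f"p{i}": {key(f"S{i % 4}")} for i in range(20)}
        dcy = {f"n{i}": {key(f"S{i % 5}")} for i in range(50)}
        filt = set()
        prev = evaluate_filter(filt, fi, dcy)
        for name in ["S0", "S1", "S2", "S3"]:
            filt = filt | {key(name)}
            report = evaluate_filter(filt, fi, dcy)
            assert report.sensitivity >= prev.sensitivity
            assert report.specificity <= prev.specificity
            prev = report


class TestSelectFilter:
    def _score(self, name, p, chi2_p):
        from faahscreen.scoring import ScaffoldScore

        return ScaffoldScore(key(name), 1, 1, p, chi2_p, None)

    def test_p_threshold_mode(self):
        scores = [self._score("hi", 3.2, 0.5), self._score("lo", 2.9, 0.001)]
        chosen = select_filter_scaffolds(scores, "p_threshold", threshold=3.0)
        assert chosen == {key("hi")}

    def test_significance_mode(self):
        scores = [self._score("sig", 5.0, 0.001), self._score("insig", 5.0, 0.2),
                  self._score("depleted", 0.5, 0.001)]
        chosen = select_filter_scaffolds(scores, "significance")
        assert chosen == {key("sig")}


class TestRepurposingScore:
    PR = {key("A"): 6.0, key("B"): 8.0}
    BM = {key("S", "BM"): 7.0}

    def test_mean_pr_plus_bm(self):
        rps = repurposing_score({key("A"), key("B")}, key("S", "BM"), self.PR, self.BM)
        assert rps == pytest.approx(14.0)

    def test_missing_terms_contribute_zero(self):
        assert repurposing_score(set(), key("T", "BM"), self.PR, self.BM) == 0.0
        assert repurposing_score({key("A")}, None, self.PR, {}) == pytest.approx(6.0)

    def test_non_filter_rings_ignored(self):
        rps = repurposing_score({key("A"), key("unscored")}, None, self.PR, {})
        assert rps == pytest.approx(6.0)


class TestRocThreshold:
    def test_class_boundary_at_target_sensitivity(self):
        scores = [2, 4, 6, 8, 10, 1, 3, 5, 7, 9]
        labels = [1] * 5 + [0] * 5
        report = rps_threshold(scores, labels, target_sensitivity=0.8)
        # 4 of the 5 positives sit strictly above the threshold
        assert 3.0 <= report.threshold < 4.0
        assert report.sensitivity == pytest.approx(0.8)
        # negatives strictly above the threshold: {5, 7, 9}
        assert report.specificity == pytest.approx(0.4)

    def test_full_sensitivity(self):
        report = threshold_at_sensitivity([5, 6, 7, 1, 2], [1, 1, 1, 0, 0], 1.0)
        assert report.threshold < 5.0
        assert report.sensitivity == 1.0

    def test_perfect_separation_auc(self):
        report = rps_threshold([10, 9, 8, 1, 2, 3], [1, 1, 1, 0, 0, 0], 0.9)
        assert report.auc == 1.0


class TestRankAUC:
    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 9), st.booleans()), min_size=4, max_size=30))
    def test_matches_pairwise_concordance(self, pairs):
        scores = np.array([float(s) for s, _ in pairs])
        labels = np.array([int(l) for _, l in pairs])
        if labels.sum() in (0, len(labels)):
            return
        pos, neg = scores[labels == 1], scores[labels == 0]
        concordant = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        oracle = concordant / (len(pos) * len(neg))
        assert rank_auc(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_agrees_with_reference_implementation(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        scores = rng.normal(size=200) + np.repeat([0.0, 1.0], 100)
        labels = np.repeat([0, 1], 100)
        assert rank_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestLibraryStatistics:
    def test_null_fraction(self):
        assign = {
            "a": {ScaffoldKey("BM", "", True)},
            "b": {key("S", "BM")},
            "c": {ScaffoldKey("BM", "", True)},
            "d": {key("S", "BM")},
        }
        assert null_fraction(assign) == pytest.approx(0.5)

    def test_exclusive_coverage(self):
        fi = {"a": {key("X", "MF")}, "b": {key("Y", "MF")}, "c": {key("Y", "MF")}}
        dcy = {"d": {key("Y", "MF")}, "e": {key("Z", "MF")}}
        cov = exclusive_coverage(fi, dcy)
        assert cov["n_exclusive"] == 1 and cov["n_shared"] == 1
        assert cov["n_covered"] == 1
        assert cov["pct_covered"] == pytest.approx(100 / 3)
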