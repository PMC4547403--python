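"""Class weights, BA/AUC, LOOCV scoring, permutation p-values, selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mirmark as mm
from mirmark.errors import ConfigError, DegenerateFoldError, DegenerateInputError
from mirmark.markers import (
    KIND_MIRNA,
    MarkerPerformance,
    loocv_ba,
    null_ba_distribution,
)


class TestClassWeights:
    def test_study_cohort_weight(self):
        w = mm.compute_class_weights(104, 17)
        assert w.w_cancer == 1.0
        assert w.w_normal == pytest.approx(6.117647, abs=1e-6)

    def test_balanced_cohort(self):
        assert mm.compute_class_weights(10, 10).w_normal == 1.0

    def test_hand_ratio(self):
        assert mm.compute_class_weights(60, 12).w_normal == pytest.approx(5.0)

    def test_zero_count_rejected(self):
        with pytest.raises(ConfigError):
            mm.compute_class_weights(0, 5)


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "tp,fn,tn,fp,expected",
        [
            (17, 0, 104, 0, 1.0),
            (104, 0, 0, 17, 0.5),  # all-cancer degenerate caller
            (100, 4, 12, 5, (100 / 104 + 12 / 17) / 2),
        ],
    )
    def test_hand_cases(self, tp, fn, tn, fp, expected):
        assert mm.balanced_accuracy(tp, fn, tn, fp) == pytest.approx(expected)

    def test_empty_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            mm.balanced_accuracy(0, 0, 5, 5)

    @given(
        st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
    )
    def test_label_swap_complement(self, tp, fn, tn, fp):
        """Swapping the positive/negative roles complements BA to 1."""
        if tp + fn == 0 or tn + fp == 0:
            return
        ba = mm.balanced_accuracy(tp, fn, tn, fp)
        assert 0.0 <= ba <= 1.0
        assert ba + mm.balanced_accuracy(fn, tp, fp, tn) == pytest.approx(1.0)


class TestAuc:
    def test_exhaustive_pair_count_example(self):
        # cancer {3,1}, normal {2,0}: 3 concordant of 4 pairs
        auc = mm.auc_from_scores([3.0, 1.0, 2.0, 0.0], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_perfect_ranking(self):
        assert mm.auc_from_scores([5, 4, 1, 0], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_all_ties(self):
        assert mm.auc_from_scores([1, 1, 1, 1], [1, 1, 0, 0]) == pytest.approx(0.5)

    def test_one_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            mm.auc_from_scores([1, 2], [1, 1])


class TestLoocvScores:
    def test_separable_feature_gives_perfect_ba(self, separable_feature):
        x, y = separable_feature()
        weights = mm.compute_class_weights(8, 4)
        pred, dec = mm.loocv_scores(x, y, weights)
        assert (pred == y).all()
        assert loocv_ba(pred, y) == 1.0
        assert mm.auc_from_scores(dec, y) == 1.0

    def test_agrees_with_brute_force_threshold_classifier(self, separable_feature):
        """On well-separated data LOOCV SVM = best threshold rule per fold."""
        x, y = separable_feature(n_cancer=10, n_normal=6, gap=8.0, seed=4)
        weights = mm.compute_class_weights(10, 6)
        pred, _ = mm.loocv_scores(x, y, weights)
        for i in range(x.size):
            mask = np.ones(x.size, bool)
            mask[i] = False
            xt, yt = x[mask], y[mask]
            # exhaustive threshold search (direction: cancer high)
            cuts = np.sort(xt)
            best = max(
                ((cuts[j] + cuts[j + 1]) / 2 for j in range(xt.size - 1)),
                key=lambda t: loocv_ba((xt > t).astype(int), yt),
            )
            assert pred[i] == int(x[i] > best)

    def test_null_feature_ba_never_looks_like_a_marker(self):
        """Null features stay far below the selection thresholds.

        Note: with w_normal = n_cancer/n_normal the weighted class masses
        balance exactly, so on a null feature the SVM often returns the
        constant classifier, which under LOOCV always favors the training
        majority, i.e. votes against the held-out sample. Mean null BA is
        therefore ~0.33, not 0.50 (simulation oracle, identical under
        libsvm); permutation p-values stay calibrated because the null BAs
        carry the same artifact.
        """
        rng = np.random.default_rng(0)
        bas = []
        weights = mm.compute_class_weights(15, 10)
        for rep in range(30):
            x = rng.normal(size=25)
            y = rng.permutation(np.r_[np.ones(15, int), np.zeros(10, int)])
            pred, _ = mm.loocv_scores(x, y, weights)
            bas.append(loocv_ba(pred, y))
        assert 0.20 < np.mean(bas) < 0.50
        assert max(bas) < 0.95

    def test_degenerate_fold_surfaced(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1, 1, 1, 0])
        with pytest.raises(DegenerateFoldError):
            mm.loocv_scores(x, y, mm.ClassWeights())

    def test_loocv_locality(self):
        """Changing sample i's label cannot change sample i's prediction."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = np.r_[np.ones(12, int), np.zeros(8, int)]
        weights = mm.ClassWeights(1.0, 1.5)
        pred, _ = mm.loocv_scores(x, y, weights)
        for i in (0, 7, 15):
            y2 = y.copy()
            y2[i] = 1 - y2[i]
            if min(y2.sum(), y2.size - y2.sum()) < 2:
                continue
            pred2, _ = mm.loocv_scores(x, y2, weights)
            assert pred2[i] == pred[i]

    def test_two_feature_joint_mode_runs(self, separable_feature):
        x, y = separable_feature(n_cancer=8, n_normal=5, gap=6.0)
        X = np.vstack([x, -x])
        pred, dec = mm.loocv_scores(X, y, mm.compute_class_weights(8, 5))
        assert loocv_ba(pred, y) == 1.0


class TestPermutationPvalue:
    def test_formula_with_observed_above_all_nulls(self, separable_feature):
        x, y = separable_feature(n_cancer=20, n_normal=10, gap=12.0, seed=1)
        weights = mm.compute_class_weights(20, 10)
        p, null = mm.permutation_pvalue(x, y, weights, n_perm=99, seed=2)
        # observed BA = 1.0 can be matched but never exceeded; with a strong
        # margin no permutation reaches it here
        assert null.size == 99
        assert p == pytest.approx(1 / 100)

    def test_observed_equal_to_every_null_gives_one(self, separable_feature):
        x, y = separable_feature(n_cancer=6, n_normal=4, gap=5.0)
        weights = mm.ClassWeights()
        null_pool = np.ones(50)
        p, _ = mm.permutation_pvalue(x, y, weights, null_pool=null_pool)
        assert p == 1.0

    def test_p_never_below_resolution(self, separable_feature):
        x, y = separable_feature(n_cancer=10, n_normal=5, gap=10.0)
        weights = mm.compute_class_weights(10, 5)
        p, null = mm.permutation_pvalue(x, y, weights, n_perm=19, seed=0)
        assert p >= 1 / (null.size + 1)

    def test_null_distribution_reproducible(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        y = np.r_[np.ones(14, int), np.zeros(6, int)]
        w = mm.compute_class_weights(14, 6)
        a = null_ba_distribution(x, y, w, mm.SVMConfig(), 25, seed=42)
        b = null_ba_distribution(x, y, w, mm.SVMConfig(), 25, seed=42)
        np.testing.assert_array_equal(a, b)


class TestSelection:
    def _perf(self, fid, kind, ba, auc, adj_p):
        return MarkerPerformance((fid,), kind, ba=ba, auc=auc, perm_p=adj_p / 2, adj_p=adj_p)

    def test_threshold_boundaries_are_strict(self):
        thr = mm.SelectionThresholds()
        good = self._perf("m", KIND_MIRNA, 0.85, 0.85, 0.01)
        assert thr.passes(good)
        assert not thr.passes(self._perf("m", KIND_MIRNA, 0.80, 0.85, 0.01))
        assert not thr.passes(self._perf("m", KIND_MIRNA, 0.85, 0.80, 0.01))
        assert not thr.passes(self._perf("m", KIND_MIRNA, 0.85, 0.85, 0.05))
        assert not thr.passes(self._perf("m", KIND_MIRNA, 0.85, 0.85, 0.06))

    def test_discovery_selects_planted_markers(self, small_cohort, small_edges):
        mirna, mrna, ann, truth = small_cohort
        filtered = mm.filter_edges(small_edges, mirna, mrna)
        result = mm.discover_markers(mirna, mrna, ann, filtered, n_perm=25, seed=3)
        assert result.selected_pairs, "strong planted markers should be selected"
        marker_edges = {
            (m, g) for m, g, _ in truth.true_edges if m in truth.marker_mirnas
        }
        selected = set(result.selected_pairs)
        # every selected pair must come from the filtered edge set
        assert selected <= filtered.keys()
        # most planted marker edges are recovered
        assert len(selected & marker_edges) / len(marker_edges) > 0.6
        # adjusted p monotone in perm p and >= perm p
        for p in result.performances:
            assert p.adj_p >= p.perm_p
            assert p.adj_p <= 1.0

    def test_empty_edge_set_warns_and_returns_empty(self, small_cohort):
        mirna, mrna, ann, _ = small_cohort
        result = mm.discover_markers(mirna, mrna, ann, mm.EdgeSet(), n_perm=5, seed=0)
        assert result.performances == []
        assert result.selected_pairs == []
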