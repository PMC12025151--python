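import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from anglemech.metrics import (
    ConfusionCounts,
    MetricInputError,
    binary_metrics,
    chi_square_accuracy_diff,
    cohens_kappa,
    confusion,
    multiclass_accuracy,
    proportion_ci,
    roc_auc,
)


class TestConfusion:
    def test_all_true(self):
        c = confusion([True] * 5, [True] * 5)
        assert (c.tp, c.fp, c.fn, c.tn) == (5, 0, 0, 0)

    def test_complement_prediction(self):
        rng = np.random.default_rng(0)
        t = rng.random(20) > 0.5
        c = confusion(t, ~t)
        assert c.tp == 0 and c.tn == 0
        assert c.fp + c.fn == 20

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_elementwise_tally(self, seed):
        rng = np.random.default_rng(seed)
        t, p = rng.random(50) > 0.4, rng.random(50) > 0.6
        c = confusion(t, p)
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for ti, pi in zip(t, p):
            tally[("tp" if pi else "fn") if ti else ("fp" if pi else "tn")] += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (
            tally["tp"], tally["fp"], tally["fn"], tally["tn"]
        )

    def test_length_mismatch(self):
        with pytest.raises(MetricInputError):
            confusion([True], [True, False])


class TestBinaryMetrics:
    def test_worked_example(self):
        rep = binary_metrics(ConfusionCounts(tp=8, fp=2, fn=1, tn=9))
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.sensitivity == pytest.approx(8 / 9, abs=1e-4)
        assert rep.specificity == pytest.approx(9 / 11, abs=1e-4)
        assert rep.ppv == pytest.approx(0.8)
        assert rep.npv == pytest.approx(0.9)
        assert rep.f1 == pytest.approx(16 / 19, abs=1e-4)
        assert rep.mcc == pytest.approx(0.7035, abs=1e-4)

    def test_perfect_classifier(self):
        rep = binary_metrics(ConfusionCounts(tp=7, fp=0, fn=0, tn=13))
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f1", "mcc"):
            assert getattr(rep, name) == pytest.approx(1.0)

    def test_all_positive_predictions_flag_npv_undefined(self):
        rep = binary_metrics(ConfusionCounts(tp=5, fp=5, fn=0, tn=0))
        assert np.isnan(rep.npv)
        assert np.isnan(rep.ci["npv"][0])
        assert np.isnan(rep.mcc)  # zero row in the table

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t, p = rng.random(60) > 0.5, rng.random(60) > 0.5
        c = confusion(t, p)
        rep = binary_metrics(c)
        tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
        assert rep.accuracy == pytest.approx(np.mean(t == p), abs=1e-12)
        if tp + fn and tn + fp and tp + fp and tn + fn:
            assert rep.sensitivity == pytest.approx(tp / (tp + fn), abs=1e-12)
            assert rep.mcc == pytest.approx(
                (tp * tn - fp * fn)
                / np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))),
                abs=1e-12,
            )


class TestWilsonCI:
    def test_k_equals_n_touches_one(self):
        low, high = proportion_ci(30, 30)
        assert high == pytest.approx(1.0)
        assert 0.0 <= low < 1.0

    def test_half_successes_symmetric(self):
        low, high = proportion_ci(50, 100)
        assert low == pytest.approx(0.4038, abs=1e-3)
        assert high == pytest.approx(0.5962, abs=1e-3)
        assert (low + high) / 2 == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("k,n", [(0, 10), (3, 17), (99, 100), (250, 1000)])
    def test_matches_statsmodels_wilson(self, k, n):
        low, high = proportion_ci(k, n)
        sm_low, sm_high = proportion_confint(k, n, alpha=0.05, method="wilson")
        assert low == pytest.approx(sm_low, abs=1e-10)
        assert high == pytest.approx(sm_high, abs=1e-10)
        assert 0.0 <= low <= high <= 1.0

    def test_invalid_counts(self):
        with pytest.raises(MetricInputError):
            proportion_ci(5, 4)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, curve = roc_auc([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert auc == 1.0
        assert curve[0].tolist() == [0.0, 0.0]
        assert curve[-1].tolist() == [1.0, 1.0]

    def test_constant_scores_give_half(self):
        auc, _ = roc_auc([0.5] * 10, [True] * 4 + [False] * 6)
        assert auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(30), 1)  # coarse grid forces ties
        labels = rng.random(30) > 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        auc, _ = roc_auc(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.random(40)
        labels = rng.random(40) > 0.5
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(3 * scores) + 1, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(MetricInputError):
            roc_auc([0.1, 0.9], [True, True])


class TestChiSquare:
    def test_identical_proportions(self):
        stat, p = chi_square_accuracy_diff(30, 40, 30, 40)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_worked_example(self):
        stat, p = chi_square_accuracy_diff(90, 100, 70, 100)
        assert stat == pytest.approx(12.5, abs=1e-9)
        assert p == pytest.approx(4.07e-4, rel=1e-2)

    def test_symmetric_in_groups(self):
        s1, _ = chi_square_accuracy_diff(55, 80, 60, 90)
        s2, _ = chi_square_accuracy_diff(60, 90, 55, 80)
        assert s1 == pytest.approx(s2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_contingency(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = int(rng.integers(20, 100)), int(rng.integers(20, 100))
        ca, cb = int(rng.integers(1, n_a)), int(rng.integers(1, n_b))
        stat, p = chi_square_accuracy_diff(ca, n_a, cb, n_b)
        table = [[ca, n_a - ca], [cb, n_b - cb]]
        ref = sps.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestKappa:
    def test_identical_raters(self):
        assert cohens_kappa(["a", "b", "a"], ["a", "b", "a"]) == pytest.approx(1.0)

    def test_worked_2x2_table(self):
        # both-pos 20, A-only 5, B-only 10, both-neg 15 -> kappa 0.4
        a = [1] * 25 + [0] * 25
        b = [1] * 20 + [0] * 5 + [1] * 10 + [0] * 15
        assert cohens_kappa(a, b) == pytest.approx(0.4, abs=1e-12)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(11)
        kappas = [
            cohens_kappa(rng.integers(0, 2, 500), rng.integers(0, 2, 500))
            for _ in range(20)
        ]
        assert max(abs(k) for k in kappas) <= 0.12
        assert abs(np.mean(kappas)) <= 0.03

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, 80)
        b = np.where(rng.random(80) < 0.6, a, rng.integers(0, 3, 80))
        assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_kappa_equals_mcc_for_symmetric_marginals(self):
        # known identity on 2x2 tables with equal off-diagonal counts
        a = np.array([1] * 30 + [0] * 30, dtype=bool)
        b = np.concatenate([np.ones(22), np.zeros(8), np.ones(8), np.zeros(22)]) > 0
        from anglemech.metrics import binary_metrics, confusion

        kappa = cohens_kappa(a, b)
        mcc = binary_metrics(confusion(a, b)).mcc
        assert kappa == pytest.approx(mcc, abs=1e-12)


class TestMulticlass:
    def test_identical(self):
        acc, table = multiclass_accuracy(["x", "y"], ["x", "y"])
        assert acc == 1.0
        assert np.trace(table) == 2

    def test_disjoint(self):
        acc, _ = multiclass_accuracy(["x", "x"], ["y", "y"])
        assert acc == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        classes = ["PURE_PB", "PURE_NON_PB", "MM", "OTHERS"]
        t = rng.choice(classes, 40)
        p = rng.choice(classes, 40)
        acc, table = multiclass_accuracy(t, p, classes=classes)
        assert acc == pytest.approx(sum(a == b for a, b in zip(t, p)) / 40, abs=1e-12)
        assert table.sum() == 40
        idx = {c: i for i, c in enumerate(classes)}
        for a, b in zip(t, p):
            table[idx[a], idx[b]] -= 1
        assert (table == 0).all()


class TestPropertyInvariants:
    """Seeded property tests of the metric invariants."""

    @staticmethod
    @given(k=st.integers(0, 200), extra=st.integers(0, 200))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_wilson_interval_well_ordered_and_bounded(k, extra):
        n = k + extra
        if n == 0:
            return
        low, high = proportion_ci(k, n)
        assert 0.0 <= low <= k / n <= high <= 1.0

    @staticmethod
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=40),
        st.data(),
    )
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_auc_complement_symmetry(scores, data):
        labels = np.array(
            data.draw(st.lists(st.booleans(), min_size=len(scores), max_size=len(scores)))
        )
        if labels.all() or not labels.any():
            return
        scores = np.asarray(scores)
        auc, _ = roc_auc(scores, labels)
        flipped, _ = roc_auc(-scores, labels)
        assert auc + flipped == pytest.approx(1.0, abs=1e-12)

    @staticmethod
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_rates_stay_in_unit_interval(tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        rep = binary_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f1"):
            v = getattr(rep, name)
            assert np.isnan(v) or 0.0 <= v <= 1.0
        assert np.isnan(rep.mcc) or -1.0 <= rep.mcc <= 1.0
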