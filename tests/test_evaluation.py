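import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

import promlm as P
from promlm.evaluation import ConfusionCounts, summarize


def standard_metrics(tp, tn, fp, fn):
    """Classical TP/TN/FP/FN closed forms (independent of the Chou forms)."""
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / (tp + tn + fp + fn)
    den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / den) if den > 0 else 0.0
    return sens, spec, acc, mcc


class TestMakeFolds:
    def test_ten_samples_five_folds(self):
        plan = P.make_folds(np.array([0, 1] * 5), n_folds=5, seed=0)
        sizes = np.bincount(plan.assignments)
        assert sizes.tolist() == [2] * 5

    def test_benchmark_sized_fold_sizes(self):
        y = np.array([1] * 3382 + [0] * 3382)
        plan = P.make_folds(y, seed=1)
        sizes = sorted(np.bincount(plan.assignments))
        assert sizes == [1352, 1353, 1353, 1353, 1353]

    def test_deterministic(self):
        y = np.array([0, 1] * 30)
        a = P.make_folds(y, seed=4)
        b = P.make_folds(y, seed=4)
        assert np.array_equal(a.assignments, b.assignments)

    def test_partition_property(self):
        y = np.array([0, 1] * 17)
        plan = P.make_folds(y, seed=2)
        seen = np.zeros(len(y), dtype=int)
        for _, va in plan.split():
            seen += va
        assert np.all(seen == 1)

    def test_stratification_preserves_proportions(self):
        y = np.array([1] * 20 + [0] * 80)
        plan = P.make_folds(y, seed=0)
        for f in range(5):
            assert y[plan.assignments == f].sum() == 4

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            P.make_folds(np.array([1, 0, 0, 0, 0, 0]), n_folds=5)


class TestConfusion:
    def test_all_correct(self):
        c = P.confusion([1] * 5 + [0] * 5, [1] * 5 + [0] * 5)
        assert (c.tp, c.tn, c.fp, c.fn) == (5, 5, 0, 0)

    def test_all_wrong(self):
        c = P.confusion([1, 1, 0, 0], [0, 0, 1, 1])
        assert (c.tp, c.tn) == (0, 0) and (c.fp, c.fn) == (2, 2)

    def test_matches_bruteforce_tally(self, rng):
        yt = rng.integers(0, 2, 200)
        yp = rng.integers(0, 2, 200)
        c = P.confusion(yt, yp)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for t, p in zip(yt, yp):
            key = ("tp" if p else "fn") if t else ("fp" if p else "tn")
            tally[key] += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (tally["tp"], tally["tn"],
                                            tally["fp"], tally["fn"])

    def test_chou_aliases(self):
        c = ConfusionCounts(tp=3, tn=4, fp=2, fn=1)
        assert c.n_pos == 4 and c.n_neg == 6
        assert c.neg_as_pos == 2 and c.pos_as_neg == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            P.confusion([0, 1], [0])


class TestChouMetrics:
    def test_perfect_classifier(self):
        rep = P.chou_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (rep.sens, rep.spec, rep.acc, rep.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_chou_equals_standard_forms_random_tables(self, rng):
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 500, 4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            rep = P.chou_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            s, p, a, m = standard_metrics(tp, tn, fp, fn)
            assert np.isclose(rep.sens, s, atol=1e-12)
            assert np.isclose(rep.spec, p, atol=1e-12)
            assert np.isclose(rep.acc, a, atol=1e-12)
            assert np.isclose(rep.mcc, m, atol=1e-10)
            assert -1 <= rep.mcc <= 1

    def test_balanced_accuracy_identity(self, rng):
        # on balanced designs Acc = (Sens+Spec)/2 exactly
        for _ in range(50):
            n = int(rng.integers(10, 400))
            fn = int(rng.integers(0, n + 1))
            fp = int(rng.integers(0, n + 1))
            rep = P.chou_metrics(ConfusionCounts(n - fn, n - fp, fp, fn))
            assert np.isclose(rep.acc, (rep.sens + rep.spec) / 2, atol=1e-12)

    def test_degenerate_mcc_reported_zero_with_flag(self):
        # every call positive: one margin is empty, MCC undefined -> 0 + flag
        rep = P.chou_metrics(ConfusionCounts(tp=5, tn=0, fp=5, fn=0))
        assert rep.mcc == 0.0 and rep.mcc_degenerate

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            P.chou_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_percent_rounding_half_up(self):
        rep = P.MetricsReport(sens=0.82765, spec=0.5, acc=0.854075, mcc=0.7085)
        out = rep.as_percent(2)
        assert out["Sens"] == 82.77  # 82.765 rounds half-up at 2 d.p.
        assert out["Acc"] == 85.41


class TestRocAuc:
    def test_perfect_ordering(self):
        _, auc = P.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_inverted_ordering(self):
        _, auc = P.roc_auc([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1])
        assert auc == 0.0

    def test_matches_pairwise_oracle_with_ties(self, rng):
        y = rng.integers(0, 2, 30)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, 30)
        s = rng.integers(0, 6, 30).astype(float)  # heavy ties
        _, auc = P.roc_auc(y, s)
        pos = s[y == 1]
        neg = s[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert np.isclose(auc, wins / (len(pos) * len(neg)), atol=1e-12)

    def test_trapezoid_equals_mann_whitney(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = rng.normal(size=n)
            points, auc = P.roc_auc(y, s)
            trap = np.trapezoid(points[:, 1], points[:, 0])
            assert np.isclose(trap, auc, atol=1e-12)

    def test_score_negation_symmetry(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.permutation(40).astype(float)  # tie-free
        _, a1 = P.roc_auc(y, s)
        _, a2 = P.roc_auc(y, -s)
        assert np.isclose(a1 + a2, 1.0, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            P.roc_auc([1, 1], [0.1, 0.2])


def wilcoxon_enumeration_oracle(a, b):
    """Exhaustive 2^n sign-pattern enumeration with midranks."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w >= obs - 1e-12:
            count += 1
    return count / 2 ** n


class TestWilcoxon:
    def test_all_positive_differences_n10(self):
        a = np.arange(10) + 1.0
        b = np.arange(10)
        assert np.isclose(P.wilcoxon_one_sided(a, b), 1 / 1024)

    def test_identical_samples_rejected(self):
        x = np.arange(8).astype(float)
        with pytest.raises(ValueError, match="zero"):
            P.wilcoxon_one_sided(x, x)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            assert np.isclose(P.wilcoxon_one_sided(a, b),
                              wilcoxon_enumeration_oracle(a, b))

    def test_matches_enumeration_with_ties(self, rng):
        a = rng.integers(0, 4, 10).astype(float)
        b = rng.integers(0, 4, 10).astype(float)
        while np.all(a == b):
            a = rng.integers(0, 4, 10).astype(float)
        assert np.isclose(P.wilcoxon_one_sided(a, b),
                          wilcoxon_enumeration_oracle(a, b))

    def test_agrees_with_scipy_exact_tie_free(self, rng):
        a = rng.normal(size=14)
        b = rng.normal(size=14)
        ours = P.wilcoxon_one_sided(a, b)
        ref = scipy_wilcoxon(a, b, alternative="greater", method="exact").pvalue
        assert np.isclose(ours, ref)

    def test_large_n_normal_approximation(self, rng):
        a = rng.normal(0.4, 1, 60)
        b = rng.normal(0.0, 1, 60)
        ours = P.wilcoxon_one_sided(a, b)
        ref = scipy_wilcoxon(a, b, alternative="greater",
                             method="approx", correction=True).pvalue
        assert np.isclose(ours, ref, rtol=1e-6)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="5"):
            P.wilcoxon_one_sided([1, 2], [0, 1])


class _StubPipeline:
    """Deterministic classifier keyed on a planted coordinate."""

    def fit(self, records, y):
        return self

    def predict(self, records):
        return np.array([1 if r.bases[10:16] == "TTGACA" else 0 for r in records])

    def decision_scores(self, records):
        return self.predict(records).astype(float)


class TestRepeatedCv:
    def test_stub_identical_across_repeats(self, tiny_layer1):
        _, l1, _ = tiny_layer1
        res = P.repeated_cv(lambda seed: _StubPipeline(), l1, n_repeats=3,
                            base_seed=1)
        assert len(res) == 15
        per_repeat = res.groupby("repeat")["acc"].mean()
        assert per_repeat.nunique() == 1  # perfect rule: identical every repeat

    def test_row_bookkeeping(self, tiny_layer1):
        _, l1, _ = tiny_layer1
        res = P.repeated_cv(lambda seed: _StubPipeline(), l1, n_repeats=2)
        assert set(res["repeat"]) == {0, 1}
        assert set(res["fold"]) == set(range(5))
        assert len(res) == 10

    def test_summarize_shape(self, tiny_layer1):
        _, l1, _ = tiny_layer1
        res = P.repeated_cv(lambda seed: _StubPipeline(), l1, n_repeats=2)
        summ = summarize(res)
        assert list(summ.index) == ["sens", "spec", "acc", "mcc", "auc"]
        assert summ["mean"].between(0, 1).all()
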