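"""Agreement statistics against hand computations and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from vaval import (
    INDETERMINATE,
    CauseList,
    UndefinedKappaError,
    agreement_indicator,
    cohen_kappa,
    contingency,
    csmf,
    csmf_tolerance_check,
    kappa_strength,
    multirater_kappa,
    pairwise_kappa,
    two_by_two,
)


def brute_kappa(a, b):
    """Oracle: Cohen's kappa straight from paired label vectors."""
    n = len(a)
    p_a = sum(x == y for x, y in zip(a, b)) / n
    cats = sorted(set(a) | set(b))
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    return (p_a - p_e) / (1 - p_e)


def brute_fleiss(assignments_by_subject, categories):
    """Oracle: Fleiss' kappa from the defining formula, loops and all."""
    n = len(assignments_by_subject)
    m = len(assignments_by_subject[0])
    p_i = []
    for labels in assignments_by_subject:
        s = sum(labels.count(c) ** 2 for c in categories)
        p_i.append((s - m) / (m * (m - 1)))
    p_bar = sum(p_i) / n
    p_j = [sum(labels.count(c) for labels in assignments_by_subject) / (n * m)
           for c in categories]
    p_e = sum(q * q for q in p_j)
    return (p_bar - p_e) / (1 - p_e)


class TestCSMF:
    def test_worked_fractions(self):
        labels = ["hiv"] * 38 + ["meningitis"] * 9 + ["other"] * 98
        cl = CauseList(("hiv", "meningitis", "other"))
        table = csmf(labels, cl)
        assert table.n_total == 145
        assert table.percentages()["hiv"] == 26.2
        assert table.percentages()["meningitis"] == 6.2

    def test_single_cause_cohort(self):
        cl = CauseList(("a", "b"))
        table = csmf(["a"] * 10, cl)
        assert table.fractions["a"] == 1.0 and table.fractions["b"] == 0.0

    def test_sums_to_one_with_indeterminate(self):
        cl = CauseList(("a", "b"))
        table = csmf(["a", "b", INDETERMINATE, "a"], cl)
        assert abs(table.fractions.sum() - 1) < 1e-12
        assert table.fractions[INDETERMINATE] == 0.25

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            csmf([], CauseList(("a",)))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            csmf(["zzz"], CauseList(("a",)))


class TestToleranceCheck:
    def test_identical_tables_pass(self):
        cl = CauseList(("a", "b"))
        t = csmf(["a", "b"], cl)
        out = csmf_tolerance_check(t, t, 0.0)
        assert out["within_tolerance"].all()

    def test_hiv_fractions_within_five_points(self):
        cl = CauseList(("hiv", "other"))
        method = csmf(["hiv"] * 38 + ["other"] * 107, cl)  # 26.2%
        gold = csmf(["hiv"] * 33 + ["other"] * 112, cl)  # 22.8%
        out = csmf_tolerance_check(method, gold, 0.05)
        assert out.loc["hiv", "within_tolerance"]

    def test_seven_point_gap_fails_five_point_tolerance(self):
        cl = CauseList(("a", "b"))
        method = csmf(["a"] * 10 + ["b"] * 90, cl)
        gold = csmf(["a"] * 3 + ["b"] * 97, cl)
        out = csmf_tolerance_check(method, gold, 0.05)
        assert not out.loc["a", "within_tolerance"]


class TestContingency:
    def test_identical_vectors_diagonal(self):
        v = ["a", "b", "a", "c"]
        t = contingency(v, v, ("a", "b", "c"))
        assert np.trace(t.to_numpy()) == 4 and t.to_numpy().sum() == 4

    def test_disjoint_assignments_zero_diagonal(self):
        t = contingency(["a", "a"], ["b", "b"], ("a", "b"))
        assert np.trace(t.to_numpy()) == 0

    def test_matches_manual_crosstab(self):
        a = ["x", "x", "y", "z", "y", "x"]
        b = ["x", "y", "y", "z", "x", "x"]
        t = contingency(a, b, ("x", "y", "z"))
        assert t.loc["x", "x"] == 2 and t.loc["x", "y"] == 1
        assert t.loc["y", "y"] == 1 and t.loc["y", "x"] == 1
        assert t.loc["z", "z"] == 1

    def test_indeterminate_gets_own_row_and_column(self):
        t = contingency(["a", INDETERMINATE], ["a", "a"], ("a",))
        assert INDETERMINATE in t.index and INDETERMINATE in t.columns
        assert t.loc[INDETERMINATE, "a"] == 1

    def test_unpaired_vectors_rejected(self):
        with pytest.raises(ValueError):
            contingency(["a"], ["a", "b"], ("a", "b"))


class TestCohenKappa:
    def test_identical_raters_kappa_one(self):
        t = pd.DataFrame([[10, 0], [0, 5]])
        res = cohen_kappa(t)
        assert res.kappa == pytest.approx(1.0)
        assert res.strength == "very good"

    def test_uniform_table_kappa_zero(self):
        res = cohen_kappa(pd.DataFrame([[25, 25], [25, 25]]))
        assert res.kappa == pytest.approx(0.0, abs=1e-12)
        assert res.p_a == pytest.approx(0.5) and res.p_e == pytest.approx(0.5)

    def test_hand_worked_three_by_three(self):
        t = pd.DataFrame([[10, 2, 0], [1, 12, 3], [0, 2, 10]])
        res = cohen_kappa(t)
        assert res.p_a == pytest.approx(0.8)
        assert res.p_e == pytest.approx(0.34)
        assert res.kappa == pytest.approx(0.697, abs=5e-4)

    def test_matches_sklearn_on_random_vectors(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(10, 50))
            k = int(rng.integers(2, 5))
            a = [f"c{i}" for i in rng.integers(0, k, n)]
            b = [f"c{i}" for i in rng.integers(0, k, n)]
            if len(set(a)) == 1 and a == b:
                continue
            cats = tuple(f"c{i}" for i in range(k))
            ours = cohen_kappa(contingency(a, b, cats)).kappa
            theirs = sklearn_metrics.cohen_kappa_score(a, b)
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_ci_brackets_kappa_and_shrinks_with_n(self):
        t = pd.DataFrame([[10, 2, 0], [1, 12, 3], [0, 2, 10]])
        small = cohen_kappa(t)
        big = cohen_kappa(t * 100)
        assert small.ci_low <= small.kappa <= small.ci_high
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)
        assert big.kappa == pytest.approx(small.kappa)

    def test_constant_identical_raters_undefined(self):
        with pytest.raises(UndefinedKappaError):
            cohen_kappa(pd.DataFrame([[7, 0], [0, 0]]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(arrays(np.int64, (3, 3), elements=st.integers(0, 30)))
    def test_symmetry_and_range(self, counts):
        t = pd.DataFrame(counts)
        n = counts.sum()
        p = counts / n if n else counts
        if n == 0 or np.isclose((p.sum(1) @ p.sum(0)), 1.0):
            return  # empty or degenerate table: covered elsewhere
        res = cohen_kappa(t)
        res_t = cohen_kappa(t.T)
        assert res.kappa == pytest.approx(res_t.kappa, abs=1e-12)
        assert -1.0 - 1e-9 <= res.kappa <= 1.0 + 1e-9
        if res.kappa == pytest.approx(1.0):
            off = counts.copy()
            np.fill_diagonal(off, 0)
            assert off.sum() == 0


class TestPairwiseKappa:
    def test_indeterminate_never_agrees_even_with_itself(self):
        a = ["a", INDETERMINATE, "b", INDETERMINATE]
        b = ["a", INDETERMINATE, "b", "a"]
        res = pairwise_kappa(a, b, ("a", "b"))
        # only the two real agreements count: P_A = 2/4
        assert res.p_a == pytest.approx(0.5)

    def test_drop_policy_removes_indeterminate_cases(self):
        a = ["a", INDETERMINATE, "b", "b"]
        b = ["a", "a", "b", "a"]
        res = pairwise_kappa(a, b, ("a", "b"), indeterminate_policy="drop")
        assert res.n == 3


class TestMultiraterKappa:
    def test_unanimous_raters_kappa_one(self):
        v = ["a", "b", "c", "a", "b"] * 4
        res = multirater_kappa(v, v, v, ("a", "b", "c"), n_bootstrap=50)
        assert res.kappa == pytest.approx(1.0)

    def test_hand_worked_fleiss_example(self):
        # 6 subjects, 3 raters, 2 categories
        subj = [["x", "x", "x"], ["x", "x", "y"], ["x", "y", "y"],
                ["y", "y", "y"], ["x", "x", "x"], ["y", "x", "x"]]
        r1, r2, r3 = (list(col) for col in zip(*subj))
        res = multirater_kappa(r1, r2, r3, ("x", "y"), n_bootstrap=50, seed=1)
        assert res.kappa == pytest.approx(brute_fleiss(subj, ("x", "y")),
                                          abs=1e-12)

    def test_matches_statsmodels_fleiss(self):
        inter_rater = pytest.importorskip("statsmodels.stats.inter_rater")
        rng = np.random.default_rng(5)
        labels = np.array(["a", "b", "c"])
        r1, r2, r3 = (list(labels[rng.integers(0, 3, 60)]) for _ in range(3))
        ours = multirater_kappa(r1, r2, r3, ("a", "b", "c"),
                                n_bootstrap=50).kappa
        counts, _ = inter_rater.aggregate_raters(
            np.array([r1, r2, r3]).T, n_cat=None)
        theirs = inter_rater.fleiss_kappa(counts)
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_two_rater_fleiss_close_to_cohen_on_balanced_data(self):
        # cross-check, not an identity: the two statistics differ in their
        # chance model but nearly coincide when marginals are balanced
        rng = np.random.default_rng(8)
        truth = rng.integers(0, 3, 600)
        noisy = np.where(rng.random(600) < 0.7, truth, rng.integers(0, 3, 600))
        a = [f"c{i}" for i in truth]
        b = [f"c{i}" for i in noisy]
        cats = ("c0", "c1", "c2")
        ck = cohen_kappa(contingency(a, b, cats)).kappa
        subj = [[x, y] for x, y in zip(a, b)]
        fk = brute_fleiss(subj, cats + (INDETERMINATE,))
        assert abs(ck - fk) < 0.02

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(9)
        truth = [f"c{i}" for i in rng.integers(0, 4, 200)]
        noisy = [t if rng.random() < 0.8 else f"c{rng.integers(0, 4)}"
                 for t in truth]
        res = multirater_kappa(truth, noisy, truth, tuple(f"c{i}" for i in
                                                          range(4)),
                               n_bootstrap=300, seed=2)
        assert res.ci_low <= res.kappa <= res.ci_high

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            multirater_kappa(["a"], ["a", "b"], ["a"], ("a", "b"))


class TestKappaStrength:
    @pytest.mark.parametrize(
        "value,label",
        [(0.52, "moderate"), (0.32, "fair"), (0.90, "very good"),
         (0.10, "poor"), (-0.5, "poor"), (0.21, "fair"), (0.40, "fair"),
         (0.41, "moderate"), (0.60, "moderate"), (0.61, "good"),
         (0.80, "good"), (0.81, "very good"), (1.0, "very good")],
    )
    def test_scale(self, value, label):
        assert kappa_strength(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kappa_strength(1.5)


class TestTwoByTwo:
    def test_perfect_prediction(self):
        gold = ["x"] * 10 + ["y"] * 90
        t = two_by_two(gold, gold, "x")
        assert (t.sensitivity[0], t.specificity[0]) == (100.0, 100.0)
        assert (t.ppv[0], t.npv[0]) == (100.0, 100.0)

    def test_direct_formula_arithmetic(self):
        # TP=5, FN=2, FP=3, TN=135
        pred = (["x"] * 5 + ["y"] * 2 + ["x"] * 3 + ["y"] * 135)
        gold = (["x"] * 5 + ["x"] * 2 + ["y"] * 3 + ["y"] * 135)
        t = two_by_two(pred, gold, "x")
        assert (t.tp, t.fn, t.fp, t.tn) == (5, 2, 3, 135)
        assert t.sensitivity[0] == pytest.approx(71.4, abs=0.05)
        assert t.specificity[0] == pytest.approx(97.8, abs=0.05)
        assert t.ppv[0] == pytest.approx(62.5, abs=0.05)
        assert t.npv[0] == pytest.approx(98.5, abs=0.05)

    def test_never_assigned_cause_has_undefined_ppv(self):
        pred = ["y"] * 10
        gold = ["x"] * 3 + ["y"] * 7
        t = two_by_two(pred, gold, "x")
        assert t.sensitivity[0] == 0.0
        assert t.ppv == (None, None, None)

    def test_ci_is_exact_binomial(self):
        proportion = pytest.importorskip("statsmodels.stats.proportion")
        t = two_by_two(["x"] * 5 + ["y"] * 5, ["x"] * 7 + ["y"] * 3, "x")
        lo, hi = proportion.proportion_confint(t.tp, t.tp + t.fn,
                                               method="beta")
        assert t.sensitivity[1] == pytest.approx(100 * lo)
        assert t.sensitivity[2] == pytest.approx(100 * hi)

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(5, 50))
            pred = [f"c{i}" for i in rng.integers(0, 3, n)]
            gold = [f"c{i}" for i in rng.integers(0, 3, n)]
            t = two_by_two(pred, gold, "c0")
            tp = sum(p == "c0" and g == "c0" for p, g in zip(pred, gold))
            fp = sum(p == "c0" and g != "c0" for p, g in zip(pred, gold))
            fn = sum(p != "c0" and g == "c0" for p, g in zip(pred, gold))
            tn = n - tp - fp - fn
            assert (t.tp, t.fp, t.fn, t.tn) == (tp, fp, fn, tn)


class TestAgreementIndicator:
    @pytest.mark.parametrize(
        "labels,expected",
        [(("hiv", "hiv", "tb"), 1),
         (("hiv", "tb", "cvd"), 0),
         (("hiv", "hiv", "hiv"), 1),
         (("tb", "hiv", "hiv"), 1),
         ((INDETERMINATE, INDETERMINATE, "hiv"), 0)],
    )
    def test_two_of_three_rule(self, labels, expected):
        assert agreement_indicator(*labels) == expected
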