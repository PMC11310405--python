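import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as scipy_stats

from mpnlp.stats import (ContingencyTable2x2, build_cohort_report,
                         cohort_report_from_counts, fisher_exact,
                         logistic_regression, odds_ratio_ci,
                         two_proportion_test)


def _enumeration_oracle(a, b, c, d, slack=1 + 1e-7):
    """Brute-force two-sided Fisher p: sum hypergeometric point probabilities
    over the support that do not exceed the observed one."""
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = scipy_stats.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    return float(pmf[pmf <= rv.pmf(a) * slack].sum())


def test_fisher_small_table_equals_enumeration():
    table = ContingencyTable2x2(2, 3, 3, 2)
    assert fisher_exact(table).p_value == pytest.approx(
        _enumeration_oracle(2, 3, 3, 2), abs=1e-12)


def test_fisher_degenerate_margin():
    res = fisher_exact(ContingencyTable2x2(0, 5, 0, 5))
    assert res.p_value == 1.0 and res.degenerate


def test_fisher_sidedness():
    table = ContingencyTable2x2(20, 63, 31, 246)
    two = fisher_exact(table).p_value
    greater = fisher_exact(table, "greater").p_value
    less = fisher_exact(table, "less").p_value
    assert greater < two < 1.0
    assert greater + less >= 1.0  # the observed table is counted in both tails
    with pytest.raises(ValueError):
        fisher_exact(table, "both")


@given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20),
       st.integers(0, 20))
def test_fisher_matches_oracle_and_transposition(a, b, c, d):
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return
    p = fisher_exact(ContingencyTable2x2(a, b, c, d)).p_value
    assert p == pytest.approx(_enumeration_oracle(a, b, c, d), abs=1e-12)
    # invariance under simultaneous row/column transposition
    assert p == pytest.approx(
        fisher_exact(ContingencyTable2x2(a, c, b, d)).p_value, abs=1e-12)


def test_table_invariants():
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        ContingencyTable2x2(0, 0, 0, 0)


def test_two_proportion_equal_rates_give_p_one():
    res = two_proportion_test(10, 100, 20, 200)
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_two_proportion_degenerate():
    res = two_proportion_test(0, 5, 0, 5)
    assert res.degenerate and res.p_value == 1.0
    res = two_proportion_test(5, 5, 7, 7)
    assert res.degenerate and res.p_value == 1.0
    with pytest.raises(ValueError):
        two_proportion_test(6, 5, 0, 5)


def test_two_proportion_matches_permutation_oracle():
    """Overall-TE comparison vs a label-shuffle randomization oracle."""
    x1, n1, x2, n2 = 43, 560, 51, 360
    res = two_proportion_test(x1, n1, x2, n2)
    rng = np.random.default_rng(2024)
    reps = 100_000
    draws = rng.hypergeometric(x1 + x2, n1 + n2 - x1 - x2, n1, size=reps)
    obs = abs(x1 / n1 - x2 / n2)
    stat = np.abs(draws / n1 - (x1 + x2 - draws) / n2)
    p_perm = float(np.mean(stat >= obs - 1e-12))
    se = math.sqrt(p_perm * (1 - p_perm) / reps)
    assert abs(res.p_value - p_perm) <= 3 * se


def test_two_proportion_monotone_in_effect_size():
    pvals = []
    for x1 in range(30, 61, 5):  # pooled total fixed, |p1 - p2| increasing
        pvals.append(two_proportion_test(x1, 200, 60 - x1, 200).p_value)
    assert all(p1 >= p2 for p1, p2 in zip(pvals, pvals[1:]))


def test_odds_ratio_symmetry_and_arithmetic():
    or_, lo, hi = odds_ratio_ci(ContingencyTable2x2(10, 10, 10, 10))
    assert or_ == pytest.approx(1.0)
    assert lo < 1.0 < hi
    or_, lo, hi = odds_ratio_ci(ContingencyTable2x2(15, 104, 28, 413))
    assert or_ == pytest.approx(15 * 413 / (104 * 28))
    assert lo < or_ < hi


def test_odds_ratio_zero_cell_correction():
    or_, lo, hi = odds_ratio_ci(ContingencyTable2x2(5, 0, 3, 7))
    assert np.isfinite(or_) and np.isfinite(hi) and lo > 0
    assert or_ == pytest.approx(5.5 * 7.5 / (0.5 * 3.5))


def test_logistic_intercept_only_closed_form():
    y = np.array([1] * 30 + [0] * 70)
    fit = logistic_regression(np.empty((100, 0)), y)
    assert fit.converged
    assert fit.params.loc["intercept", "coef"] == pytest.approx(
        math.log(0.3 / 0.7), abs=1e-8)


def test_logistic_single_covariate_equals_2x2_log_odds_ratio():
    rng = np.random.default_rng(5)
    for _ in range(5):
        x = rng.integers(0, 2, 300)
        p = np.where(x == 1, 0.55, 0.25)
        y = (rng.random(300) < p).astype(int)
        a = int(np.sum((x == 1) & (y == 1)))
        b = int(np.sum((x == 1) & (y == 0)))
        c = int(np.sum((x == 0) & (y == 1)))
        d = int(np.sum((x == 0) & (y == 0)))
        if min(a, b, c, d) == 0:
            continue
        fit = logistic_regression(x.astype(float), y)
        assert fit.params.loc["x0", "coef"] == pytest.approx(
            math.log(a * d / (b * c)), abs=1e-6)


def test_logistic_matches_reference_mle():
    rng = np.random.default_rng(6)
    X = rng.integers(0, 2, (400, 3)).astype(float)
    beta = np.array([-1.0, 0.9, -0.4, 0.3])
    y = (rng.random(400) < 1 / (1 + np.exp(-(beta[0] + X @ beta[1:])))).astype(int)
    fit = logistic_regression(pd.DataFrame(X, columns=["a", "b", "c"]), y)
    import statsmodels.api as sm
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert np.allclose(fit.params["coef"].to_numpy(), ref.params, atol=1e-7)
    assert np.allclose(fit.params["se"].to_numpy(), ref.bse, atol=1e-7)


def test_logistic_flags_separation_and_suppresses_cis():
    x = np.array([0.0] * 20 + [1.0] * 20)
    y = np.array([0] * 20 + [1] * 20)
    fit = logistic_regression(x, y)
    assert fit.separation
    assert fit.params["ci_low"].isna().all()


def test_logistic_input_validation():
    with pytest.raises(ValueError, match="constant"):
        logistic_regression(np.ones(20), np.array([0, 1] * 10))
    with pytest.raises(ValueError, match="lengths"):
        logistic_regression(np.array([0.0, 1.0]), np.array([0, 1, 0]))


def test_identical_cohorts_give_p_one(vocab):
    from mpnlp.vocab import CVA, DVT
    idx = pd.Index([f"p{i}" for i in range(40)], name="patient_id")
    pheno = pd.DataFrame({CVA: [1] * 10 + [0] * 30, DVT: [1] * 5 + [0] * 35},
                         index=idx)
    report = build_cohort_report(pheno, pheno, label_a="ET", label_b="PV")
    assert (report["p_unadjusted"] == 1.0).all()
    assert (report["method"] == "two_proportion_z").all()


def test_single_patient_cohorts_degenerate_but_no_crash():
    from mpnlp.vocab import CVA
    a = pd.DataFrame({CVA: [0]}, index=pd.Index(["p1"], name="patient_id"))
    b = pd.DataFrame({CVA: [0]}, index=pd.Index(["q1"], name="patient_id"))
    report = build_cohort_report(a, b)
    assert report["degenerate"].all()


def test_report_from_counts_shape():
    report = cohort_report_from_counts({"CVA": (43, 51), "PE": (10, 10)},
                                       560, 360, "ET", "PV")
    assert list(report["event"]) == ["CVA", "PE"]
    assert report.at[0, "pct_ET"] == pytest.approx(100 * 43 / 560)
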