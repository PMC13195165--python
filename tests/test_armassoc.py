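"""Per-arm regressions, exact binomial sign tests (with enumeration
oracles), ANOVA, and arm-vector correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cstelo import armassoc


# ---------------------------------------------------------------------------
# p-value printing

@pytest.mark.parametrize("p,printed", [
    (1.8189894035458565e-12, "2e-12"),
    (1.4703843771712855e-4, "0.0001"),
    (1.6889239559532143e-3, "0.002"),
    (2.662595704896376e-2, "0.03"),
    (0.26, "0.3"),
    (0.953, "1"),
])
def test_format_p_one_significant_figure(p, printed):
    assert armassoc.format_p(p) == printed


# ---------------------------------------------------------------------------
# sign test

def test_sign_test_printed_values_all_directions():
    """The canonical k-of-39 cases: exact tails and one-sided CP bounds."""
    cases = {
        39: ("2e-12", 1.00, 0.93),
        31: ("0.0001", 0.79, 0.66),
        29: ("0.002", 0.74, 0.60),
        26: ("0.03", 0.67, 0.52),
    }
    for k, (printed, p_hat, ci_lo) in cases.items():
        betas = [-1.0] * k + [1.0] * (39 - k)
        res = armassoc.sign_binomial(betas, "negative")
        assert res.pvalue_printed == printed
        assert res.p_hat == pytest.approx(p_hat, abs=0.005)
        assert round(res.ci_lower, 2) == ci_lo
        assert res.ci == (res.ci_lower, 1.0)


def test_sign_test_exact_tail_sum_oracle():
    from math import comb
    for k in (39, 31, 29, 26):
        betas = [-1.0] * k + [1.0] * (39 - k)
        res = armassoc.sign_binomial(betas, "negative")
        oracle = sum(comb(39, j) for j in range(k, 40)) / 2**39
        assert res.pvalue == pytest.approx(oracle, rel=1e-12)


@given(st.integers(1, 12), st.integers(0, 2**31 - 1))
def test_sign_test_matches_exhaustive_enumeration(n, seed):
    """For small n, enumerate all 2^n sign patterns: the p-value is the
    exact probability of >= k successes under fair coin flips."""
    rng = np.random.default_rng(seed)
    betas = rng.normal(0, 1, n)
    betas[betas == 0] = 1.0
    k = int((betas < 0).sum())
    res = armassoc.sign_binomial(betas, "negative")
    count = sum(
        1 for signs in itertools.product([0, 1], repeat=n) if sum(signs) >= k
    )
    assert res.pvalue == pytest.approx(count / 2**n, rel=1e-12)


# ---------------------------------------------------------------------------
# per-arm OLS

def _cohort_table(n=400, beta_age=-30.0, seed=0, n_arms=10):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        age = rng.normal(50, 15)
        for a in range(n_arms):
            y = 4000 + beta_age * (age - 50) + rng.normal(0, 600)
            rows.append((f"s{i}", f"arm{a:02d}", age, y))
    return pd.DataFrame(rows, columns=["sample_id", "arm", "age", "cstl_bp"])


def test_exposure_duplicated_as_adjuster_rejected():
    tab = _cohort_table(20)
    with pytest.raises(ValueError, match="duplicated"):
        armassoc.per_arm_ols(tab, "age", ("age",))


def test_uniform_age_effect_recovered():
    tab = _cohort_table(n=300, beta_age=-30.0, seed=3)
    res = armassoc.per_arm_ols(tab, "age")
    assert (res["beta"] < 0).all()
    assert res["beta"].mean() == pytest.approx(-30, abs=3)


def test_null_exposure_calibrated():
    rng = np.random.default_rng(9)
    hits, total = 0, 0
    for rep in range(10):
        tab = _cohort_table(n=120, beta_age=0.0, seed=100 + rep, n_arms=10)
        tab["noise"] = tab["sample_id"].map(
            dict(zip(tab["sample_id"].unique(),
                     rng.normal(0, 1, tab["sample_id"].nunique()))))
        res = armassoc.per_arm_ols(tab, "noise")
        hits += (res["pvalue"] < 0.05).sum()
        total += len(res)
    assert 0.005 < hits / total < 0.12


# ---------------------------------------------------------------------------
# ANOVA

def test_anova_df_and_two_group_t_identity():
    tab = _cohort_table(n=100, n_arms=2, seed=5)
    f, df1, df2, p, _ = armassoc.arm_anova(tab)
    assert df1 == 1
    a = tab[tab.arm == "arm00"]["cstl_bp"]
    b = tab[tab.arm == "arm01"]["cstl_bp"]
    t, _ = stats.ttest_ind(a, b)
    assert f == pytest.approx(t**2, rel=1e-10)


def test_anova_39_levels_df():
    tab = _cohort_table(n=30, n_arms=39, seed=6)
    f, df1, df2, p, means = armassoc.arm_anova(tab)
    assert df1 == 38
    assert len(means) == 39


def test_anova_null_f_near_one():
    fs = [armassoc.arm_anova(_cohort_table(n=60, n_arms=8, seed=s))[0]
          for s in range(20, 30)]
    assert 0.5 < np.mean(fs) < 1.6


# ---------------------------------------------------------------------------
# arm-vector correlations

def test_linear_and_monotone_correlations():
    x = pd.Series(np.arange(10.0), index=[f"a{i}" for i in range(10)])
    y = 2 * x + 1
    r, _ = armassoc.arm_vector_correlation(x, y, "pearson")
    assert r == pytest.approx(1.0)
    z = np.exp(x / 3.0)
    rho, _ = armassoc.arm_vector_correlation(x, z, "spearman")
    assert rho == pytest.approx(1.0)
    rp, _ = armassoc.arm_vector_correlation(x, z, "pearson")
    assert rp < 1.0


def test_too_few_common_arms_rejected():
    x = pd.Series([1.0, 2.0], index=["a", "b"])
    y = pd.Series([1.0, 2.0], index=["b", "c"])
    with pytest.raises(ValueError, match="common arms"):
        armassoc.arm_vector_correlation(x, y)


def test_slope_magnitude_tracks_arm_mean(small_truth_table, small_cohort):
    """With positive slope-mean coupling in the generator, |age slope|
    correlates positively with arm mean csTL across the 39 arms."""
    assoc = armassoc.per_arm_ols(small_truth_table, "age")
    means = small_truth_table.groupby("arm")["cstl_bp"].mean()
    r, p = armassoc.arm_vector_correlation(
        means, assoc.set_index("arm")["beta"].abs())
    assert r > 0
    assert p < 0.05
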