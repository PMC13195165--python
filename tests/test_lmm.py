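"""Crossed-LMM correctness: dense-likelihood oracle, closed-form limits,
variance partitioning, LRT machinery, and the random-slope interaction."""

import numpy as np
import pandas as pd
import pytest

from cstelo import lmm
from conftest import crossed_dataset


# ---------------------------------------------------------------------------
# dense multivariate-normal oracle

def dense_loglik(df, s_ind, s_arm, s_e, criterion, fixed=("age",)):
    """Direct evaluation of the (restricted) Gaussian log-likelihood from
    the fully materialized n x n covariance, with beta at GLS."""
    n = len(df)
    X, _ = lmm.build_fixed_design(df, fixed)
    y = df["cstl_bp"].to_numpy()
    Z1 = pd.get_dummies(df["sample_id"]).to_numpy(float)
    Z2 = pd.get_dummies(df["arm"]).to_numpy(float)
    V = s_e * np.eye(n) + s_ind * Z1 @ Z1.T + s_arm * Z2 @ Z2.T
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    ll = -0.5 * (n * np.log(2 * np.pi) + np.linalg.slogdet(V)[1] + r @ Vi @ r)
    if criterion == "ML":
        return ll
    p = X.shape[1]
    return ll + 0.5 * p * np.log(2 * np.pi) \
        - 0.5 * np.linalg.slogdet(X.T @ Vi @ X)[1]


@pytest.mark.parametrize("criterion", ["ML", "REML"])
@pytest.mark.parametrize("seed", [1, 2, 3])
def test_objective_matches_dense_oracle(criterion, seed):
    df = crossed_dataset(seed, n_ind=18, n_arm=7)   # ~110 records
    assert len(df) <= 200
    fit = lmm.fit_lmm(df, ("age",), criterion=criterion)
    mine = fit.model.loglik_at(fit.sigma2_e, fit.sigma2_ind, fit.sigma2_arm,
                               criterion=criterion)
    oracle = dense_loglik(df, fit.sigma2_ind, fit.sigma2_arm, fit.sigma2_e,
                          criterion)
    assert mine == pytest.approx(oracle, abs=1e-6)
    assert fit.loglik == pytest.approx(mine, abs=1e-6)
    # off-optimum point too
    mine2 = fit.model.loglik_at(2.0, 1.0, 4.0, criterion=criterion)
    oracle2 = dense_loglik(df, 1.0, 4.0, 2.0, criterion)
    assert mine2 == pytest.approx(oracle2, abs=1e-6)


def test_pure_noise_reduces_to_ols():
    rng = np.random.default_rng(0)
    df = crossed_dataset(4, n_ind=25, n_arm=8, s_ind=0.0, s_arm=0.0, s_e=2.0)
    fit = lmm.fit_lmm(df, ("age",), criterion="REML")
    assert fit.sigma2_ind < 0.25
    assert fit.sigma2_arm < 0.25
    import statsmodels.api as sm
    X, _ = lmm.build_fixed_design(df, ("age",))
    ols = sm.OLS(df["cstl_bp"].to_numpy(), X).fit()
    np.testing.assert_allclose(fit.beta.to_numpy(), ols.params, atol=0.05)


def test_balanced_oneway_matches_anova_moments():
    """Balanced one-way layout (arm effect only): REML variance equals the
    classical method-of-moments estimator (MSB - MSW) / n."""
    rng = np.random.default_rng(10)
    A, m = 12, 40
    b = rng.normal(0, 3.0, A)
    rows = []
    for a in range(A):
        for j in range(m):
            rows.append((f"s{a}_{j}", f"arm{a:02d}",
                         20 + b[a] + rng.normal(0, 1.2)))
    df = pd.DataFrame(rows, columns=["sample_id", "arm", "cstl_bp"])
    y = df["cstl_bp"].to_numpy().reshape(A, m)
    msb = m * y.mean(axis=1).var(ddof=1)
    msw = y.var(axis=1, ddof=1).mean()
    mom = (msb - msw) / m
    fit = lmm.fit_lmm(df, (), random=("arm",), criterion="REML")
    assert fit.sigma2_arm == pytest.approx(mom, rel=1e-4)
    assert fit.sigma2_e == pytest.approx(msw, rel=1e-4)


def test_component_recovery_and_invariance():
    df = crossed_dataset(7, n_ind=120, n_arm=12, s_ind=4.0, s_arm=9.0, s_e=2.25)
    fit = lmm.fit_lmm(df, ("age",))
    assert fit.sigma2_ind == pytest.approx(4.0, rel=0.5)
    assert fit.sigma2_arm == pytest.approx(9.0, rel=0.8)
    assert fit.sigma2_e == pytest.approx(2.25, rel=0.15)
    # invariance to record order and to relabeling
    shuf = df.sample(frac=1, random_state=1).reset_index(drop=True)
    shuf["sample_id"] = "x" + shuf["sample_id"]
    fit2 = lmm.fit_lmm(shuf, ("age",))
    assert fit2.sigma2_ind == pytest.approx(fit.sigma2_ind, rel=1e-4)
    assert fit2.sigma2_arm == pytest.approx(fit.sigma2_arm, rel=1e-4)
    assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-5)


def test_collinear_design_names_columns():
    df = crossed_dataset(1)
    df["age_copy"] = df["age"]
    with pytest.raises(lmm.LMMError, match="age_copy"):
        lmm.fit_lmm(df, ("age", "age_copy"))


# ---------------------------------------------------------------------------
# PVE

def test_pve_sums_to_one_and_intercept_only_zero():
    df = crossed_dataset(5)
    dec = lmm.pve(lmm.fit_lmm(df, ("age",)))
    assert dec.table["pve"].sum() == pytest.approx(1.0, abs=1e-9)
    dec0 = lmm.pve(lmm.fit_lmm(df, ()))
    assert dec0.pve("fixed") == 0.0


def test_noise_covariate_contributes_little():
    df = crossed_dataset(6, n_ind=80, n_arm=10)
    rng = np.random.default_rng(11)
    df["noise"] = rng.standard_normal(len(df))
    r2, test = lmm.covariate_contribution(df, "noise")
    assert r2 < 0.01
    assert test.pvalue > 0.01


# ---------------------------------------------------------------------------
# LRT

def test_identical_models_give_chi2_zero():
    df = crossed_dataset(2)
    full = lmm.fit_lmm(df, ("age",), criterion="ML")
    full2 = lmm.fit_lmm(df, ("age",), criterion="ML")
    # same spec: df would be 0 -> non-nested error
    with pytest.raises(lmm.LMMError, match="nested"):
        lmm.lrt(full, full2)
    red = lmm.fit_lmm(df, (), criterion="ML")
    r = lmm.lrt(full, red)
    assert r.chi2 >= 0 and r.df == 1


def test_extreme_chi2_reports_log_scale():
    r = lmm.LRTResult(
        chi2=1845.4, df=1,
        pvalue=float(__import__("scipy.stats", fromlist=["chi2"]).chi2.sf(1845.4, 1)),
        log10_pvalue=float(
            __import__("scipy.stats", fromlist=["chi2"]).chi2.logsf(1845.4, 1)
            / np.log(10)),
    )
    assert r.pvalue == 0.0            # underflows
    assert r.log10_pvalue < -300      # but the log-scale value is finite


def test_criterion_mismatch_rejected():
    df = crossed_dataset(3)
    a = lmm.fit_lmm(df, ("age",), criterion="ML")
    b = lmm.fit_lmm(df, (), criterion="REML")
    with pytest.raises(lmm.LMMError, match="criterion"):
        lmm.lrt(a, b)


# ---------------------------------------------------------------------------
# random slope / interaction

def test_homogeneous_slopes_small_chi2():
    df = crossed_dataset(8, n_ind=60, n_arm=10, beta_age=-0.3)
    res = lmm.age_by_arm_interaction(df)
    assert res.df == 2
    assert res.pvalue > 0.01


def test_heterogeneous_slopes_detected_and_coupled():
    rng = np.random.default_rng(13)
    A, I = 12, 100
    arm_mean = np.linspace(2, 6, A)
    slopes = -0.02 * arm_mean            # |slope| grows with arm mean
    rows = []
    for i in range(I):
        age = rng.normal(45, 15)
        u = rng.normal(0, 0.4)
        for a in range(A):
            y = arm_mean[a] + u + slopes[a] * (age - 45) + rng.normal(0, 0.3)
            rows.append((f"s{i}", f"arm{a:02d}", age, y))
    df = pd.DataFrame(rows, columns=["sample_id", "arm", "age", "cstl_bp"])
    res = lmm.age_by_arm_interaction(df)
    assert res.pvalue < 0.01
    means = df.groupby("arm")["cstl_bp"].mean()
    from scipy.stats import pearsonr
    r, _ = pearsonr(means, res.arm_slopes.abs().loc[means.index])
    assert r > 0.5


# ---------------------------------------------------------------------------
# batch handling / three-mode agreement

def test_batch_modes_agree_on_covariate_coefficient():
    rng = np.random.default_rng(17)
    df = crossed_dataset(9, n_ind=150, n_arm=10, beta_age=-0.3)
    batches = {f"s{i:03d}": f"b{i % 4}" for i in range(150)}
    df["batch"] = df["sample_id"].map(batches)
    offs = {"b0": 0.0, "b1": 2.0, "b2": -1.5, "b3": 0.8}
    df["cstl_bp"] = df["cstl_bp"] + df["batch"].map(offs)

    fixed_fit = lmm.fit_lmm(df, ("age", "batch"))
    rand_fit = lmm.fit_lmm(df, ("age",), random=("individual", "arm", "batch"))
    from cstelo.batch import residualize_on_batch
    resid = residualize_on_batch(df)
    resid_fit = lmm.fit_lmm(resid, ("age",), value_col="cstl_resid")

    betas = np.array([fixed_fit.beta["age"], rand_fit.beta["age"],
                      resid_fit.beta["age"]])
    assert (np.sign(betas) == np.sign(betas[0])).all()
    assert np.abs(betas - betas.mean()).max() / abs(betas.mean()) < 0.10


def test_lme4_cross_validation(tmp_path):
    """Independent cross-check of REML variance components against lme4."""
    import shutil, subprocess

    df = crossed_dataset(21, n_ind=25, n_arm=8)
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        "suppressMessages(library(lme4))\n"
        f"d <- read.csv('{csv}')\n"
        "m <- lmer(cstl_bp ~ age + (1|sample_id) + (1|arm), data=d, REML=TRUE)\n"
        "vc <- as.data.frame(VarCorr(m))\n"
        "cat(vc$vcov, as.numeric(logLik(m)), sep=',')\n"
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, check=True)
    s_ind, s_arm, s_e, ll = map(float, out.stdout.strip().split(","))
    fit = lmm.fit_lmm(df, ("age",), criterion="REML")
    assert fit.sigma2_ind == pytest.approx(s_ind, rel=1e-3, abs=1e-4)
    assert fit.sigma2_arm == pytest.approx(s_arm, rel=1e-3, abs=1e-4)
    assert fit.sigma2_e == pytest.approx(s_e, rel=1e-3)
    assert fit.loglik == pytest.approx(ll, abs=1e-3)
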