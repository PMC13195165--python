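"""Disease association with telomere-length metrics.

Logistic regression of case status on a per-person TL metric — the mean
csTL across measured arms or the shortest csTL (the minimum per person, a
candidate biomarker of replicative exhaustion) — reporting odds ratios
per 1 kb of TL with Wald confidence intervals.  Individuals whose mean or
shortest TL lies more than 3 cohort standard deviations from the cohort
mean are excluded in a single pre-fit pass.  Arm-level variants fit one
logistic model per arm; a pooled mixed-model association treats disease
status as a fixed effect on csTL with crossed random effects.

Cardiovascular disease is a composite: hypertension, ischemic heart
disease, or heart failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .lmm import build_fixed_design, fit_lmm

__all__ = [
    "cvd_composite", "tl_metrics_with_exclusion", "DiseaseAssocResult",
    "logistic_or", "per_arm_disease", "pooled_lmm_disease",
]

CVD_COMPONENTS = ("hypertension", "ihd", "hf")


def cvd_composite(flags: pd.DataFrame,
                  components: Sequence[str] = CVD_COMPONENTS) -> pd.Series:
    """CVD case = any of hypertension, ischemic heart disease, heart
    failure.  Composite prevalence is >= each component's by construction."""
    missing = [c for c in components if c not in flags.columns]
    if missing:
        raise KeyError(f"missing disease flag column(s): {missing}")
    return flags[list(components)].astype(bool).any(axis=1).rename("cvd")


def tl_metrics_with_exclusion(
    summaries: pd.DataFrame, sd_bound: float = 3.0
) -> pd.DataFrame:
    """Per-person mean and shortest TL in kb, excluding individuals whose
    mean or shortest TL is more than ``sd_bound`` SDs from the cohort mean.

    Bounds are computed once on the pre-exclusion cohort (single pass, not
    iterated).  The number excluded is in ``result.attrs["n_excluded"]``.
    """
    out = summaries.copy()
    out["mean_tl_kb"] = out["mean_tl"] / 1000.0
    out["shortest_tl_kb"] = out["shortest_tl"] / 1000.0
    keep = np.ones(len(out), dtype=bool)
    for col in ("mean_tl_kb", "shortest_tl_kb"):
        mu, sd = out[col].mean(), out[col].std()
        if sd > 0:
            keep &= (out[col] - mu).abs() <= sd_bound * sd
    n_excluded = int((~keep).sum())
    out = out[keep].reset_index(drop=True)
    out.attrs["n_excluded"] = n_excluded
    return out


@dataclass
class DiseaseAssocResult:
    metric: str
    outcome: str
    odds_ratio: float          # per 1 kb increase in the TL metric
    ci: tuple[float, float]    # Wald 95%
    pvalue: float
    n_cases: int
    n_controls: int
    n_excluded: int = 0
    low_power: bool = False


def _fit_logistic(
    df: pd.DataFrame, outcome: str, metric_col: str, adjusters: Sequence[str]
) -> DiseaseAssocResult:
    y = df[outcome].astype(float).to_numpy()
    X, names = build_fixed_design(df, adjusters)
    X = np.column_stack([X, df[metric_col].to_numpy(dtype=float)])
    names = names + [metric_col]
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            raise np.linalg.LinAlgError("newton did not converge")
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        try:
            res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=1000)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            res = None
        if res is None or not np.isfinite(res.bse).all():
            raise RuntimeError(
                f"(quasi-)separation fitting {outcome} on {metric_col}; "
                f"reduce the adjuster set"
            ) from exc
        if not res.mle_retvals.get("converged", True):
            warnings.warn(f"logistic fit for {outcome} did not converge")
    j = len(names) - 1
    beta, se = res.params[j], res.bse[j]
    return DiseaseAssocResult(
        metric=metric_col, outcome=outcome,
        odds_ratio=float(np.exp(beta)),
        ci=(float(np.exp(beta - 1.959964 * se)), float(np.exp(beta + 1.959964 * se))),
        pvalue=float(res.pvalues[j]),
        n_cases=int(y.sum()), n_controls=int(len(y) - y.sum()),
    )


def logistic_or(
    metrics: pd.DataFrame,
    outcome: str,
    metric: str = "shortest_tl_kb",
    adjusters: Sequence[str] = (),
) -> DiseaseAssocResult:
    """OR per 1 kb of the chosen TL metric from a maximum-likelihood
    logistic fit, Wald 95% CI and p-value.  ``metrics`` should come from
    :func:`tl_metrics_with_exclusion` merged with covariates and disease
    flags."""
    res = _fit_logistic(metrics, outcome, metric, adjusters)
    res.n_excluded = metrics.attrs.get("n_excluded", 0)
    return res


def per_arm_disease(
    arm_table: pd.DataFrame,
    outcome: str,
    adjusters: Sequence[str] = (),
    value_col: str = "cstl_bp",
    min_cases: int = 10,
) -> pd.DataFrame:
    """Per-arm logistic OR of disease per 1 kb of that arm's csTL.

    A person enters an arm's fit only if they have an estimate for that
    arm.  Arms with fewer than ``min_cases`` cases are flagged
    ``low_power`` but still reported.
    """
    rows = []
    tab = arm_table.copy()
    tab["_cstl_kb"] = tab[value_col] / 1000.0
    for arm, grp in tab.groupby("arm", sort=True):
        if grp[outcome].astype(bool).nunique() < 2:
            warnings.warn(f"arm {arm}: outcome has one class; skipped")
            continue
        r = _fit_logistic(grp, outcome, "_cstl_kb", adjusters)
        rows.append(dict(
            arm=arm, odds_ratio=r.odds_ratio, ci_low=r.ci[0], ci_high=r.ci[1],
            pvalue=r.pvalue, n_cases=r.n_cases, n_controls=r.n_controls,
            low_power=r.n_cases < min_cases,
        ))
    return pd.DataFrame(rows)


def pooled_lmm_disease(
    arm_table: pd.DataFrame,
    outcome: str,
    adjusters: Sequence[str] = (),
    value_col: str = "cstl_bp",
) -> pd.Series:
    """Cross-arm association of disease status with csTL: a linear mixed
    model of csTL on the disease indicator plus adjusters, with crossed
    random effects of individual and arm.  Returns the disease
    coefficient (bp), its SE, and the Wald p-value."""
    tab = arm_table.copy()
    tab["_case"] = tab[outcome].astype(bool).astype(float)
    fit = fit_lmm(tab, ("_case", *adjusters), criterion="REML",
                  value_col=value_col)
    beta = fit.beta["_case"]
    se = fit.se["_case"]
    from scipy import stats as st
    z = beta / se
    return pd.Series(
        {"beta_bp": beta, "se": se, "pvalue": 2 * st.norm.sf(abs(z))},
        name=outcome,
    )
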