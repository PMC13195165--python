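"""Per-arm association analyses and cross-arm summaries.

Each of the 39 analysis arms gets its own least-squares regression of
csTL on an exposure (with optional adjusters).  Cross-arm consistency of
direction is tested with an exact one-sided binomial sign test under the
null that positive and negative associations are equally likely; the
point estimate p-hat is the fraction of arms in the stated direction,
reported with a one-sided 95% Clopper-Pearson lower bound (upper bound
fixed at 1).  One-way ANOVA of arm and arm-level vector correlations
(e.g. |age slope| vs mean csTL, or rank agreement with an external
ranking) complete the toolkit.

No multiple-testing adjustment is applied across arms; per-arm p-values
are reported as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .lmm import build_fixed_design

__all__ = [
    "per_arm_ols", "SignTestResult", "sign_binomial", "arm_anova",
    "arm_vector_correlation", "format_p",
]


def format_p(p: float) -> str:
    """Round a p-value to one significant figure, scientific notation below
    1e-4 (e.g. 1.82e-12 -> '2e-12', 1.47e-4 -> '0.0001', 0.0266 -> '0.03')."""
    if not np.isfinite(p):
        return "nan"
    if p <= 0:
        return "0"
    if p >= 1:
        return "1"
    exponent = int(np.floor(np.log10(p)))
    lead = round(p / 10.0**exponent)
    if lead == 10:
        lead, exponent = 1, exponent + 1
    if exponent < -4:
        return f"{lead}e{exponent}"
    return f"{lead * 10.0**exponent:.{max(-exponent, 0)}f}"


def per_arm_ols(
    arm_table: pd.DataFrame,
    exposure: str,
    adjusters: Sequence[str] = (),
    value_col: str = "cstl_bp",
) -> pd.DataFrame:
    """Per-arm OLS coefficient of the exposure with SE and two-sided p.

    Each arm is fit independently on its own records.  Arms with fewer
    records than design columns are omitted with a warning.
    """
    if exposure in adjusters:
        raise ValueError(f"exposure {exposure!r} duplicated among adjusters")
    rows, skipped = [], []
    for arm, grp in arm_table.groupby("arm", sort=True):
        X, names = build_fixed_design(grp, [exposure, *adjusters])
        if len(grp) <= X.shape[1]:
            skipped.append(arm)
            continue
        # the exposure's column: numeric -> its name; binary categorical ->
        # its single indicator column
        cand = [j for j, nm in enumerate(names)
                if nm == exposure or nm.startswith(f"{exposure}[")]
        if len(cand) != 1:
            raise ValueError(
                f"exposure {exposure!r} must map to one design column; got "
                f"{[names[j] for j in cand]}"
            )
        res = sm.OLS(grp[value_col].to_numpy(dtype=float), X).fit()
        j = cand[0]
        rows.append(dict(arm=arm, beta=res.params[j], se=res.bse[j],
                         pvalue=res.pvalues[j], n=int(res.nobs)))
    if skipped:
        warnings.warn(f"arm(s) omitted (too few records): {skipped}")
    return pd.DataFrame(rows)


@dataclass
class SignTestResult:
    """Exact one-sided binomial test of directional consistency across arms."""

    n_arms: int
    n_in_direction: int
    direction: str
    p_hat: float
    ci_lower: float          # one-sided 95% lower bound; upper bound is 1
    pvalue: float            # exact upper-tail P under Binomial(n, 1/2)

    @property
    def pvalue_printed(self) -> str:
        return format_p(self.pvalue)

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_lower, 1.0)


def sign_binomial(
    assoc: pd.DataFrame | Sequence[float],
    direction: str = "negative",
    alpha: float = 0.05,
    two_sided_ci: bool = False,
) -> SignTestResult:
    """Test whether per-arm associations share one direction more often
    than chance.

    ``assoc`` is a ``per_arm_ols`` result (its ``beta`` column is used) or
    a plain sequence of coefficients.  P = sum_{j>=k} C(n,j) / 2^n, the
    exact upper tail.  The CI lower bound is Clopper-Pearson: one-sided
    at level ``alpha`` by default, or the lower end of the two-sided
    (1 - alpha) interval when ``two_sided_ci``.
    """
    betas = np.asarray(
        assoc["beta"] if isinstance(assoc, pd.DataFrame) else assoc, dtype=float
    )
    n = betas.size
    if n < 1:
        raise ValueError("need at least one arm")
    if direction == "negative":
        k = int((betas < 0).sum())
    elif direction == "positive":
        k = int((betas > 0).sum())
    else:
        raise ValueError("direction must be 'positive' or 'negative'")
    pvalue = float(stats.binom.sf(k - 1, n, 0.5))
    a = alpha / 2 if two_sided_ci else alpha
    ci_lower = float(stats.beta.ppf(a, k, n - k + 1)) if k > 0 else 0.0
    return SignTestResult(
        n_arms=n, n_in_direction=k, direction=direction,
        p_hat=k / n, ci_lower=ci_lower, pvalue=pvalue,
    )


def arm_anova(
    arm_table: pd.DataFrame, value_col: str = "cstl_bp"
) -> tuple[float, int, int, float, pd.Series]:
    """One-way fixed-effects ANOVA of csTL on arm label.

    Returns (F, df1, df2, p, per-arm means); df1 = #arms - 1.  The means
    are returned sorted longest-first for ranking.
    """
    groups = [g[value_col].to_numpy(dtype=float)
              for _, g in arm_table.groupby("arm", sort=True)]
    if len(groups) < 2:
        raise ValueError("need >= 2 arms")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    means = (arm_table.groupby("arm", sort=True)[value_col].mean()
             .sort_values(ascending=False))
    return float(f), df1, df2, float(p), means


def arm_vector_correlation(
    x: pd.Series, y: pd.Series, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between two per-arm vectors aligned on common arm labels
    (inner join; >= 3 common arms required).  Spearman uses average ranks
    for ties."""
    joined = pd.concat([x.rename("x"), y.rename("y")], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError(f"only {len(joined)} common arms; need >= 3")
    if method == "pearson":
        r, p = stats.pearsonr(joined["x"], joined["y"])
    elif method == "spearman":
        r, p = stats.spearmanr(joined["x"], joined["y"])
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)
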