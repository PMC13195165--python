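"""Gaussian linear mixed models with crossed random effects.

The model for the person x arm csTL table is

    y = X beta + Z_ind u + Z_arm b [+ Z_batch c] + eps,
    u ~ N(0, sigma2_ind I),  b ~ N(0, I_arms (x) G),
    c ~ N(0, sigma2_batch I),  eps ~ N(0, sigma2_e I),

with crossed grouping factors *individual* and *chromosome arm*, and
optionally a random *batch* intercept (batch is constant within
individual).  G is a scalar (random arm intercept) or a 2x2 covariance
(intercept + random slope of a covariate, e.g. age, by arm).

Fitting profiles out beta and sigma2_e and optimizes the variance *ratios*
via a relative-covariance-factor (Cholesky) parameterization with
non-negativity enforced by bound constraints, in the style of lme4's
profiled deviance.  The normal-equation block for the individual
intercepts is diagonal, so each deviance evaluation reduces to a small
dense Schur complement over the batch/arm block — no n x n covariance is
ever materialized.

Variance partitioning follows the marginal-R2 convention: the share of a
component is its variance divided by Var(X beta-hat) plus all random and
residual variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "LMMError", "ConvergenceError", "build_fixed_design",
    "LMMFit", "fit_lmm", "pve", "VarianceDecomposition",
    "variance_decomposition", "LRTResult", "lrt",
    "covariate_contribution", "age_by_arm_interaction", "InteractionResult",
]

_LOG2PI = np.log(2.0 * np.pi)


class LMMError(RuntimeError):
    pass


class ConvergenceError(LMMError):
    pass


#: Reference levels for reference-coded categorical covariates; batch and
#: unlisted categoricals default to their most frequent level.
CATEGORICAL_REFERENCES: dict[str, str] = {
    "sex": "female",
    "smoking": "never",
    "ancestry": "AFR",
}


def build_fixed_design(
    df: pd.DataFrame, fixed: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate columns; categoricals are reference-coded
    (female / never-smoker / AFR; most frequent level otherwise).  Raises
    naming the aliased columns if the design is rank-deficient."""
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(intercept)"]
    for f in fixed:
        s = df[f]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            cols.append(s.to_numpy(dtype=float))
            names.append(f)
        else:
            s = s.astype(str)
            counts = s.value_counts()
            ref = CATEGORICAL_REFERENCES.get(f, counts.index[0])
            if ref not in counts.index:
                ref = counts.index[0]
            for lev in sorted(lv for lv in counts.index if lv != ref):
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{f}[{lev}]")
    X = np.column_stack(cols)
    r = np.linalg.qr(X, mode="r")
    dr = np.abs(np.diag(r))
    tol = dr.max() * max(X.shape) * np.finfo(float).eps * 10
    aliased = [names[j] for j in range(X.shape[1]) if dr[j] < tol]
    if aliased:
        raise LMMError(f"collinear fixed design; aliased column(s): {aliased}")
    return X, names


class _CrossedLMM:
    """Profiled-deviance machinery for one data layout.

    The individual factor occupies the diagonal block; batch and arm
    (with optional slope column) form a small dense block handled by one
    Cholesky per evaluation.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        ind_codes: np.ndarray | None,
        arm_codes: np.ndarray | None,
        slope_x: np.ndarray | None = None,
        batch_codes: np.ndarray | None = None,
    ):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.has_ind = ind_codes is not None
        self.has_arm = arm_codes is not None
        self.has_batch = batch_codes is not None
        if slope_x is not None and not self.has_arm:
            raise LMMError("a random slope requires the arm factor")
        self.d = 2 if slope_x is not None else 1

        self.I = int(ind_codes.max()) + 1 if self.has_ind else 0
        self.A = int(arm_codes.max()) + 1 if self.has_arm else 0
        self.B = int(batch_codes.max()) + 1 if self.has_batch else 0
        XY = np.column_stack([self.X, self.y])
        self.CXY = XY.T @ XY

        # small-block design per record: [batch one-hot | arm block of W]
        self.q_small = self.B + self.A * self.d
        W = None
        if self.has_arm:
            W = np.ones((self.n, self.d))
            if self.d == 2:
                W[:, 1] = slope_x

        if self.has_ind:
            self.n_i = np.bincount(ind_codes, minlength=self.I).astype(float)
            self.U_i = np.zeros((self.I, self.p + 1))
            np.add.at(self.U_i, ind_codes, XY)
        if self.q_small:
            C = np.zeros((self.q_small, self.q_small))
            U = np.zeros((self.q_small, self.p + 1))
            if self.has_batch:
                nb = np.bincount(batch_codes, minlength=self.B).astype(float)
                C[: self.B, : self.B] = np.diag(nb)
                Ub = np.zeros((self.B, self.p + 1))
                np.add.at(Ub, batch_codes, XY)
                U[: self.B] = Ub
            if self.has_arm:
                Caa = np.zeros((self.A, self.d, self.d))
                np.add.at(Caa, arm_codes, W[:, :, None] * W[:, None, :])
                for a in range(self.A):
                    s = self.B + a * self.d
                    C[s:s + self.d, s:s + self.d] = Caa[a]
                Ua = np.zeros((self.A, self.d, self.p + 1))
                np.add.at(Ua, arm_codes, W[:, :, None] * XY[:, None, :])
                U[self.B:] = Ua.reshape(self.A * self.d, self.p + 1)
            if self.has_batch and self.has_arm:
                Cba = np.zeros((self.B, self.A, self.d))
                np.add.at(Cba, (batch_codes, arm_codes), W)
                Cba = Cba.reshape(self.B, self.A * self.d)
                C[: self.B, self.B:] = Cba
                C[self.B:, : self.B] = Cba.T
            self.C_small = C
            self.U_small = U
            if self.has_ind:
                M = np.zeros((self.I, self.q_small))
                if self.has_batch:
                    np.add.at(M, (ind_codes, batch_codes), 1.0)
                if self.has_arm:
                    Mia = np.zeros((self.I, self.A, self.d))
                    np.add.at(Mia, (ind_codes, arm_codes), W)
                    M[:, self.B:] = Mia.reshape(self.I, self.A * self.d)
                self.M = M

        # theta layout: [t_ind?] + [t_batch?] + lower-tri arm factor (rows)
        self.n_theta = (
            (1 if self.has_ind else 0)
            + (1 if self.has_batch else 0)
            + (self.d * (self.d + 1) // 2 if self.has_arm else 0)
        )

    # -- theta packing ---------------------------------------------------

    def _unpack(self, theta: np.ndarray):
        k = 0
        t_ind = t_batch = 0.0
        if self.has_ind:
            t_ind = float(theta[k]); k += 1
        if self.has_batch:
            t_batch = float(theta[k]); k += 1
        lam = np.zeros((self.d, self.d))
        if self.has_arm:
            for i in range(self.d):
                for j in range(i + 1):
                    lam[i, j] = theta[k]; k += 1
        return t_ind, t_batch, lam

    def _lam_small(self, t_batch: float, lam: np.ndarray) -> np.ndarray:
        """Relative-covariance factor of the small block (diagonal for
        batch, block-diagonal Cholesky factor for arms)."""
        L = np.zeros((self.q_small, self.q_small))
        if self.has_batch:
            L[: self.B, : self.B] = t_batch * np.eye(self.B)
        if self.has_arm:
            L[self.B:, self.B:] = np.kron(np.eye(self.A), lam)
        return L

    def bounds(self) -> list[tuple[float | None, float | None]]:
        b: list[tuple[float | None, float | None]] = []
        if self.has_ind:
            b.append((0.0, None))
        if self.has_batch:
            b.append((0.0, None))
        if self.has_arm:
            for i in range(self.d):
                for j in range(i + 1):
                    b.append((0.0, None) if i == j else (None, None))
        return b

    def start(self) -> np.ndarray:
        return np.array(
            [0.6 if lo == 0.0 else 0.0 for lo, _ in self.bounds()], dtype=float
        )

    # -- profiled pieces -------------------------------------------------

    def _solve_parts(self, theta: np.ndarray):
        """logdet(A) of the scaled penalized normal equations and their
        Schur complement W over [X y]; plus intermediates for BLUPs."""
        t_ind, t_batch, lam = self._unpack(theta)
        p1 = self.p + 1
        logdetA = 0.0
        Q = np.zeros((p1, p1))
        x_i = x_s = None
        D = E = S_cf = V_i = Vs = Ls = None

        if self.has_ind:
            D = t_ind * t_ind * self.n_i + 1.0
            logdetA += np.log(D).sum()
            V_i = t_ind * self.U_i
        if self.q_small:
            Ls = self._lam_small(t_batch, lam)
            S = Ls.T @ self.C_small @ Ls + np.eye(self.q_small)
            Vs = Ls.T @ self.U_small
            if self.has_ind:
                E = t_ind * (self.M @ Ls)
                S = S - E.T @ (E / D[:, None])
            S_cf = linalg.cho_factor(S, lower=True)
            logdetA += 2.0 * np.log(np.diag(S_cf[0])).sum()
            rhs = Vs.copy()
            if self.has_ind:
                rhs -= E.T @ (V_i / D[:, None])
            x_s = linalg.cho_solve(S_cf, rhs)
            Q += Vs.T @ x_s
            if self.has_ind:
                x_i = (V_i - E @ x_s) / D[:, None]
                Q += V_i.T @ x_i
        elif self.has_ind:
            x_i = V_i / D[:, None]
            Q += V_i.T @ x_i

        W = self.CXY - Q
        return logdetA, W, (x_i, x_s, t_ind, t_batch, lam, Ls)

    def _wchol(self, W: np.ndarray):
        try:
            Lw = np.linalg.cholesky(W)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise LMMError("singular profiled normal equations") from exc
        r2 = Lw[self.p, self.p] ** 2
        logdetWxx = 2.0 * np.log(np.diag(Lw)[: self.p]).sum()
        return Lw, r2, logdetWxx

    def deviance(self, theta: np.ndarray, criterion: str) -> float:
        logdetA, W, _ = self._solve_parts(theta)
        _, r2, logdetWxx = self._wchol(W)
        n, p = self.n, self.p
        if criterion == "ML":
            return logdetA + n * (1.0 + _LOG2PI + np.log(r2 / n))
        return logdetA + logdetWxx + (n - p) * (
            1.0 + _LOG2PI + np.log(r2 / (n - p))
        )

    def loglik_at(
        self,
        sigma2_e: float,
        sigma2_ind: float = 0.0,
        arm_cov: np.ndarray | float = 0.0,
        sigma2_batch: float = 0.0,
        criterion: str = "REML",
    ) -> float:
        """Exact (restricted) log-likelihood at given variance components,
        with beta at its GLS value — the quantity a dense multivariate-
        normal evaluation returns."""
        theta = []
        if self.has_ind:
            theta.append(np.sqrt(max(sigma2_ind, 0.0) / sigma2_e))
        if self.has_batch:
            theta.append(np.sqrt(max(sigma2_batch, 0.0) / sigma2_e))
        if self.has_arm:
            G = np.atleast_2d(np.asarray(arm_cov, dtype=float))
            lam = np.linalg.cholesky(G / sigma2_e + 1e-300 * np.eye(self.d))
            for i in range(self.d):
                for j in range(i + 1):
                    theta.append(lam[i, j])
        logdetA, W, _ = self._solve_parts(np.array(theta))
        _, r2, logdetWxx = self._wchol(W)
        n, p = self.n, self.p
        if criterion == "ML":
            return -0.5 * (
                n * (_LOG2PI + np.log(sigma2_e)) + logdetA + r2 / sigma2_e
            )
        return -0.5 * (
            (n - p) * (_LOG2PI + np.log(sigma2_e))
            + logdetA + logdetWxx + r2 / sigma2_e
        )

    # -- post-fit extraction --------------------------------------------

    def solution(self, theta: np.ndarray, criterion: str):
        logdetA, W, (x_i, x_s, t_ind, t_batch, lam, Ls) = self._solve_parts(theta)
        Lw, r2, logdetWxx = self._wchol(W)
        n, p = self.n, self.p
        dof = n if criterion == "ML" else n - p
        sigma2_e = r2 / dof
        Wxx, wxy = W[:p, :p], W[:p, p]
        beta = np.linalg.solve(Wxx, wxy)
        cov_beta = sigma2_e * np.linalg.inv(Wxx)
        # BLUPs: b = Lam u*, with u* = A^{-1} Lam' Z' (y - X beta);
        # the columns of x_* solve that system for [X y]
        ranef_ind = ranef_batch = ranef_arm = None
        if self.has_ind:
            u_i = x_i[:, p] - x_i[:, :p] @ beta
            ranef_ind = t_ind * u_i
        if self.q_small:
            u_s = Ls @ (x_s[:, p] - x_s[:, :p] @ beta)
            if self.has_batch:
                ranef_batch = u_s[: self.B]
            if self.has_arm:
                ranef_arm = u_s[self.B:].reshape(self.A, self.d)
        return dict(
            sigma2_e=sigma2_e,
            sigma2_ind=t_ind * t_ind * sigma2_e if self.has_ind else 0.0,
            sigma2_batch=t_batch * t_batch * sigma2_e if self.has_batch else 0.0,
            arm_cov=sigma2_e * (lam @ lam.T) if self.has_arm else None,
            beta=beta, cov_beta=cov_beta,
            ranef_ind=ranef_ind, ranef_batch=ranef_batch, ranef_arm=ranef_arm,
            r2=r2, logdetA=logdetA, logdetWxx=logdetWxx,
        )


@dataclass
class LMMFit:
    """A fitted crossed random-effects model."""

    beta: pd.Series
    se: pd.Series
    sigma2_ind: float
    sigma2_arm: float
    sigma2_e: float
    loglik: float
    criterion: str
    converged: bool
    n_obs: int
    n_ind: int
    n_arm: int
    n_params: int
    fixed: tuple[str, ...]
    random: tuple[str, ...]
    fitted_fixed: np.ndarray
    theta: np.ndarray
    boundary: bool
    grad_norm: float
    sigma2_batch: float = 0.0
    ranef_ind: pd.Series | None = None
    ranef_arm: pd.DataFrame | None = None
    ranef_batch: pd.Series | None = None
    arm_cov: np.ndarray | None = None
    slope_on: str | None = None
    model: "_CrossedLMM" = field(repr=False, default=None)

    @property
    def sigma2_slope(self) -> float | None:
        if self.arm_cov is not None and self.arm_cov.shape[0] == 2:
            return float(self.arm_cov[1, 1])
        return None

    @property
    def slope_int_cov(self) -> float | None:
        if self.arm_cov is not None and self.arm_cov.shape[0] == 2:
            return float(self.arm_cov[0, 1])
        return None


def fit_lmm(
    arm_table: pd.DataFrame,
    fixed: Sequence[str] = (),
    random: Sequence[str] = ("individual", "arm"),
    slope_on: str | None = None,
    criterion: str = "REML",
    value_col: str = "cstl_bp",
    sample_col: str = "sample_id",
    arm_col: str = "arm",
    batch_col: str = "batch",
) -> LMMFit:
    """Fit the crossed LMM by profiled (restricted) maximum likelihood.

    ``random`` is a subset of {"individual", "arm", "batch"}; ``slope_on``
    adds a correlated random slope of the named (centered) covariate by
    arm.  Raises :class:`ConvergenceError` only on hard failures; soft
    optimizer complaints set ``converged=False`` on the returned fit.
    """
    if criterion not in ("REML", "ML"):
        raise ValueError("criterion must be 'REML' or 'ML'")
    unknown = set(random) - {"individual", "arm", "batch"}
    if unknown:
        raise ValueError(f"unknown random terms: {sorted(unknown)}")
    y = arm_table[value_col].to_numpy(dtype=float)
    X, names = build_fixed_design(arm_table, fixed)

    ind_codes = arm_codes = batch_codes = None
    ind_index = arm_index = batch_index = None
    if "individual" in random:
        cat = pd.Categorical(arm_table[sample_col])
        ind_codes, ind_index = cat.codes, cat.categories
    if "arm" in random:
        cat = pd.Categorical(arm_table[arm_col])
        arm_codes, arm_index = cat.codes, cat.categories
    if "batch" in random:
        cat = pd.Categorical(arm_table[batch_col])
        batch_codes, batch_index = cat.codes, cat.categories
    slope_x = None
    if slope_on is not None:
        sx = arm_table[slope_on].to_numpy(dtype=float)
        slope_x = sx - sx.mean()

    m = _CrossedLMM(y, X, ind_codes, arm_codes, slope_x, batch_codes)
    if m.n_theta == 0:
        theta = np.zeros(0)
        res_success, grad_norm = True, 0.0
    else:
        obj = lambda th: m.deviance(th, criterion)
        res = optimize.minimize(
            obj, m.start(), method="L-BFGS-B", bounds=m.bounds(),
            options=dict(maxiter=500, ftol=1e-13, gtol=1e-7),
        )
        # short simplex polish: tightens past the finite-difference
        # gradient tolerance (estimates then invariant to record order)
        # and rescues occasional L-BFGS-B failures
        res2 = optimize.minimize(
            obj, res.x, method="Nelder-Mead",
            options=dict(maxfev=120 * max(m.n_theta, 1),
                         xatol=1e-7, fatol=1e-11),
        )
        res_success = bool(res.success or res2.success)
        grad = getattr(res, "jac", None)
        grad_norm = float(np.linalg.norm(grad)) if grad is not None else np.nan
        if res2.fun <= res.fun:
            res = res2
        theta = np.maximum(res.x, [lo if lo is not None else -np.inf
                                   for lo, _ in m.bounds()])
        if not res_success:
            warnings.warn(f"LMM optimizer did not report convergence: {res.message}")

    sol = m.solution(theta, criterion)
    dev = m.deviance(theta, criterion)
    t_ind, t_batch, lam = m._unpack(theta)
    boundary = bool(
        (m.has_ind and t_ind < 1e-5)
        or (m.has_batch and t_batch < 1e-5)
        or (m.has_arm and np.any(np.abs(np.diag(lam)) < 1e-5))
    )
    arm_cov = sol["arm_cov"]
    return LMMFit(
        beta=pd.Series(sol["beta"], index=names),
        se=pd.Series(np.sqrt(np.diag(sol["cov_beta"])), index=names),
        sigma2_ind=float(sol["sigma2_ind"]),
        sigma2_arm=float(arm_cov[0, 0]) if arm_cov is not None else 0.0,
        sigma2_e=float(sol["sigma2_e"]),
        sigma2_batch=float(sol["sigma2_batch"]),
        loglik=-0.5 * dev,
        criterion=criterion,
        converged=res_success,
        n_obs=m.n, n_ind=m.I, n_arm=m.A,
        n_params=m.p + m.n_theta + 1,
        fixed=tuple(fixed), random=tuple(random),
        fitted_fixed=X @ sol["beta"],
        theta=np.asarray(theta, dtype=float),
        boundary=boundary,
        grad_norm=grad_norm,
        ranef_ind=(pd.Series(sol["ranef_ind"], index=ind_index)
                   if sol["ranef_ind"] is not None else None),
        ranef_arm=(pd.DataFrame(
            sol["ranef_arm"], index=arm_index,
            columns=["intercept", "slope"][: m.d])
            if sol["ranef_arm"] is not None else None),
        ranef_batch=(pd.Series(sol["ranef_batch"], index=batch_index)
                     if sol["ranef_batch"] is not None else None),
        arm_cov=arm_cov,
        slope_on=slope_on,
        model=m,
    )


# ---------------------------------------------------------------------------
# variance partitioning


@dataclass
class VarianceDecomposition:
    """Variance (bp^2) and share of total per component, with optional LRTs."""

    table: pd.DataFrame                 # component, variance, pve
    lrts: pd.DataFrame | None = None    # component, chi2, df, pvalue

    def pve(self, component: str) -> float:
        return float(self.table.set_index("component").loc[component, "pve"])


def pve(fit: LMMFit) -> VarianceDecomposition:
    """Marginal-R2 style decomposition: Var(X beta-hat) (sample variance)
    for all fixed effects jointly, plus each random-effect variance and
    the residual, each divided by their sum."""
    if fit.slope_on is not None:
        raise LMMError("variance decomposition is defined for intercept models")
    var_fixed = float(np.var(fit.fitted_fixed, ddof=1)) if len(fit.fixed) else 0.0
    comps = {
        "fixed": var_fixed,
        "individual": fit.sigma2_ind,
        "arm": fit.sigma2_arm,
        "residual": fit.sigma2_e,
    }
    if "batch" in fit.random:
        comps["batch_random"] = fit.sigma2_batch
    total = sum(comps.values())
    tab = pd.DataFrame(
        {"component": list(comps), "variance": list(comps.values()),
         "pve": [v / total for v in comps.values()]}
    )
    return VarianceDecomposition(table=tab)


@dataclass
class LRTResult:
    chi2: float
    df: int
    pvalue: float
    log10_pvalue: float


def lrt(full: LMMFit, reduced: LMMFit, tol: float = 1e-2) -> LRTResult:
    """Likelihood-ratio test of nested fits on the same records and
    criterion.  chi2 is clamped at 0; extreme statistics keep a finite
    log10 p-value even when the p-value itself underflows."""
    if full.criterion != reduced.criterion:
        raise LMMError("LRT requires fits on the same criterion")
    if full.n_obs != reduced.n_obs:
        raise LMMError("LRT requires fits on identical records")
    df = full.n_params - reduced.n_params
    if df <= 0:
        raise LMMError("models are not nested (full has no extra parameters)")
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < -tol:
        raise LMMError(
            f"full model log-likelihood below reduced ({chi2/2:.4f}); refit required"
        )
    chi2 = max(chi2, 0.0)
    return LRTResult(
        chi2=float(chi2), df=int(df),
        pvalue=float(stats.chi2.sf(chi2, df)),
        log10_pvalue=float(_chi2_logsf(chi2, df) / np.log(10.0)),
    )


def _chi2_logsf(x: float, df: int) -> float:
    """log of the chi-square upper tail, stable for statistics whose
    p-value underflows the double range."""
    v = float(stats.chi2.logsf(x, df))
    if np.isfinite(v) or x == 0:
        return v
    if df == 1:
        return float(np.log(2.0) + stats.norm.logsf(np.sqrt(x)))
    if df == 2:
        return -x / 2.0
    from scipy.special import gammaln
    # leading term of the asymptotic upper incomplete gamma expansion
    return float((df / 2 - 1) * np.log(x / 2) - x / 2 - gammaln(df / 2))


def variance_decomposition(
    arm_table: pd.DataFrame,
    fixed: Sequence[str],
    random: Sequence[str] = ("individual", "arm"),
    value_col: str = "cstl_bp",
) -> VarianceDecomposition:
    """Full-model decomposition with LRTs: the joint fixed-effect block is
    tested on ML fits, each random effect on REML fits with the identical
    fixed part."""
    full_reml = fit_lmm(arm_table, fixed, random=random, criterion="REML",
                        value_col=value_col)
    dec = pve(full_reml)

    lrts = []
    if fixed:
        full_ml = fit_lmm(arm_table, fixed, random=random, criterion="ML",
                          value_col=value_col)
        null_ml = fit_lmm(arm_table, (), random=random, criterion="ML",
                          value_col=value_col)
        r = lrt(full_ml, null_ml)
        lrts.append(("fixed", r.chi2, r.df, r.pvalue, r.log10_pvalue))
    for drop in random:
        red = fit_lmm(
            arm_table, fixed,
            random=tuple(t for t in random if t != drop),
            criterion="REML", value_col=value_col,
        )
        r = lrt(full_reml, red)
        lrts.append((drop, r.chi2, r.df, r.pvalue, r.log10_pvalue))
    dec.lrts = pd.DataFrame(
        lrts, columns=["component", "chi2", "df", "pvalue", "log10_pvalue"]
    )
    return dec


def covariate_contribution(
    arm_table: pd.DataFrame,
    covariate: str,
    random: Sequence[str] = ("individual", "arm"),
    value_col: str = "cstl_bp",
) -> tuple[float, LRTResult]:
    """Marginal R2 of a single fixed effect (its share of total variance in
    a model with only that covariate plus the random effects) and the LRT
    p-value against the random-effects-only model (ML fits)."""
    m1 = fit_lmm(arm_table, (covariate,), random=random, criterion="ML",
                 value_col=value_col)
    m0 = fit_lmm(arm_table, (), random=random, criterion="ML",
                 value_col=value_col)
    r2 = pve(m1).pve("fixed")
    return r2, lrt(m1, m0)


@dataclass
class InteractionResult:
    chi2: float
    df: int
    pvalue: float
    log10_pvalue: float
    arm_slopes: pd.Series          # predicted total slope per arm
    slope_var: float
    slope_int_cov: float
    boundary: bool


def age_by_arm_interaction(
    arm_table: pd.DataFrame,
    covariate: str = "age",
    fixed: Sequence[str] | None = None,
    value_col: str = "cstl_bp",
) -> InteractionResult:
    """Test whether the covariate's slope varies by chromosome arm.

    Compares a model with random arm intercepts to one adding a correlated
    random slope of the (centered) covariate by arm — two extra variance
    parameters (slope variance and slope-intercept covariance), so df = 2.
    Returns predicted per-arm slopes (fixed slope + BLUP deviations).
    """
    fixed = tuple(fixed) if fixed is not None else (covariate,)
    if covariate not in fixed:
        fixed = (covariate,) + fixed
    full = fit_lmm(arm_table, fixed, slope_on=covariate,
                   criterion="REML", value_col=value_col)
    red = fit_lmm(arm_table, fixed, criterion="REML", value_col=value_col)
    r = lrt(full, red)
    if full.boundary:
        warnings.warn("slope variance at the zero boundary; LRT conservative")
    beta_cov = full.beta[covariate]
    slopes = beta_cov + full.ranef_arm["slope"]
    return InteractionResult(
        chi2=r.chi2, df=r.df, pvalue=r.pvalue, log10_pvalue=r.log10_pvalue,
        arm_slopes=slopes.rename("slope"),
        slope_var=full.sigma2_slope, slope_int_cov=full.slope_int_cov,
        boundary=full.boundary,
    )
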