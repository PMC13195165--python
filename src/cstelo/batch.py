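"""Batch-effect adjustment of telomere-length estimates.

Two procedures:

1. Depth-PC residualization for average-TL estimates: principal
   components of a binned sequencing-depth matrix capture latent batch
   structure; TL is regressed on the top *k* PCs and the residual kept,
   with *k* chosen to maximize the magnitude of the residual's
   correlation with age (age being a robust external correlate of TL).
2. Categorical-batch residualization for csTL: residuals from a
   batch-means model, removing all between-batch mean differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DepthPCA", "depth_pcs", "AdjustedTL", "select_k_and_adjust",
           "residualize_on_batch"]


@dataclass
class DepthPCA:
    """SVD of the (standardized) depth matrix: per-sample scores ordered by
    decreasing explained variance."""

    scores: np.ndarray              # samples x components (U * S)
    explained_variance_ratio: np.ndarray
    singular_values: np.ndarray
    sample_ids: np.ndarray | None = None


def depth_pcs(
    depth: pd.DataFrame | np.ndarray,
    n_components: int | None = None,
    scale: bool = True,
) -> DepthPCA:
    """Principal-component scores of a samples x bins depth matrix.

    Bins are centered (and z-scored when ``scale``); zero-variance bins
    are dropped.  Scores are mutually orthogonal; ``U @ diag(S) @ Vt``
    reconstructs the centered matrix exactly when all components are kept.
    """
    ids = None
    if isinstance(depth, pd.DataFrame):
        ids = depth.index.to_numpy()
        depth = depth.to_numpy(dtype=float)
    n, m = depth.shape
    if n < 2:
        raise ValueError("need >= 2 samples")
    sd = depth.std(axis=0)
    keep = sd > 0
    x = depth[:, keep] - depth[:, keep].mean(axis=0)
    if scale:
        x = x / sd[keep]
    max_k = min(x.shape)
    if n_components is None:
        n_components = max_k
    if n_components > max_k:
        raise ValueError(f"n_components {n_components} > min(samples, bins) {max_k}")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    return DepthPCA(
        scores=(u * s)[:, :n_components],
        explained_variance_ratio=var[:n_components] / var.sum(),
        singular_values=s[:n_components],
        sample_ids=ids,
    )


@dataclass
class AdjustedTL:
    """Batch-adjusted TL values (residual scale, mean ~0)."""

    adjusted: np.ndarray
    k_used: int
    curve: pd.DataFrame          # k -> |corr(residual, age)|
    sample_ids: np.ndarray | None = None


def _residualize(y: np.ndarray, scores: np.ndarray, k: int) -> np.ndarray:
    yc = y - y.mean()
    if k == 0:
        return yc
    q, _ = np.linalg.qr(scores[:, :k])
    return yc - q @ (q.T @ yc)


def select_k_and_adjust(
    tl: np.ndarray | pd.Series,
    pcs: DepthPCA,
    age: np.ndarray | pd.Series,
    k_grid: Sequence[int] = range(0, 51),
    tol: float = 0.01,
) -> AdjustedTL:
    """Regress TL on the top-k depth PCs for each k in ``k_grid``, keep the
    residuals at the k maximizing |Pearson corr(residual, age)|, and
    report the whole k -> correlation curve.

    A larger k is preferred only when it improves the correlation by more
    than ``tol`` — chance fluctuations from regressing on components
    orthogonal to the artifact are of order 1/sqrt(n), so without a
    tolerance the argmax would drift upward on artifact-free data; exact
    ties also resolve to the smallest k.
    """
    y = np.asarray(tl, dtype=float)
    a = np.asarray(age, dtype=float)
    if np.std(y) == 0:
        raise ValueError("TL vector is constant; correlation undefined")
    ks = sorted(set(int(k) for k in k_grid))
    if ks and ks[-1] > pcs.scores.shape[1]:
        raise ValueError(
            f"k_grid max {ks[-1]} exceeds available components {pcs.scores.shape[1]}"
        )
    rows = []
    best_k, best_corr, best_res = None, -np.inf, None
    for k in ks:
        res = _residualize(y, pcs.scores, k)
        if np.std(res) == 0:
            corr = np.nan
        else:
            corr = abs(stats.pearsonr(res, a)[0])
        rows.append({"k": k, "abs_corr_age": corr})
        # improvement must exceed tol; ties resolve to the smallest k
        if np.isfinite(corr) and corr > best_corr + tol:
            best_k, best_corr, best_res = k, corr, res
    if best_k is None:
        raise ValueError("no k in grid yielded a defined correlation")
    return AdjustedTL(
        adjusted=best_res, k_used=best_k,
        curve=pd.DataFrame(rows), sample_ids=pcs.sample_ids,
    )


def residualize_on_batch(
    arm_table: pd.DataFrame,
    value_col: str = "cstl_bp",
    batch_col: str = "batch",
    out_col: str = "cstl_resid",
) -> pd.DataFrame:
    """Residuals from a batch-means model: each record minus its batch mean.

    Within-batch residual means are 0 by construction.  Batches with a
    single record get residual 0 (with a warning) — their mean is the
    record itself.
    """
    out = arm_table.copy()
    sizes = out.groupby(batch_col)[value_col].transform("size")
    if (sizes == 1).any():
        singles = out.loc[sizes == 1, batch_col].unique().tolist()
        warnings.warn(f"singleton batch(es) {singles}: residual set to 0")
    means = out.groupby(batch_col)[value_col].transform("mean")
    out[out_col] = out[value_col] - means
    return out
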