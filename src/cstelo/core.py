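"""Parsing, QC, and aggregation of per-allele telomere calls.

The input is a Telogator2-style call table: one row per allele cluster
with the 75th-percentile telomere length of its supporting reads
(``tl_p75``), the telomere-variant-repeat length (``tvr_len``), the
supporting-read count, and a flag for reads that could not be assigned to
a single chromosome arm.  The output is the person x arm csTL table that
all downstream models consume, plus per-sample summaries (telomeric
coverage, mean TL, shortest TL).

QC rules: csTL estimates shorter than 100 bp, negative TVR lengths, and
ambiguous arm assignments are excluded.  When an arm has two or more
allele estimates they are averaged; a single estimate is used as-is.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .arms import ACROCENTRIC_P, ANALYSIS_ARMS, ARM_LABELS, SEX_ARMS

__all__ = [
    "CallFormatError",
    "load_calls",
    "save_calls",
    "qc_filter",
    "collapse_to_arm",
    "resolve_duplicate_samples",
    "exclude_arms",
    "sample_summaries",
    "arm_call_rate",
    "MIN_CSTL_BP",
]

#: QC floor on per-allele TL estimates (estimates *shorter than* this are dropped).
MIN_CSTL_BP = 100.0

CALL_COLUMNS = (
    "sample_id", "arm", "allele_index", "tl_p75", "tvr_len",
    "n_supporting_reads", "mapping_ambiguous",
)


class CallFormatError(ValueError):
    """Malformed call table: missing columns or invariant-violating rows."""


def load_calls(path, strict: bool = True) -> pd.DataFrame:
    """Read a tab-separated call table.

    Mandatory columns are ``sample_id, arm, allele_index, tl_p75, tvr_len,
    n_supporting_reads``; ``mapping_ambiguous`` defaults to False if
    absent; unknown columns are preserved.  Rows violating the call
    invariants (tl_p75 < 0 or n_supporting_reads < 1) are rejected with
    their 1-based file line numbers — as an error when ``strict``,
    otherwise dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    mandatory = [c for c in CALL_COLUMNS if c != "mapping_ambiguous"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise CallFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    if "mapping_ambiguous" not in df.columns:
        df["mapping_ambiguous"] = False
    for col in ("tl_p75", "tvr_len", "n_supporting_reads"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["mapping_ambiguous"] = df["mapping_ambiguous"].astype(bool)

    bad = (
        df["tl_p75"].isna() | df["tvr_len"].isna()
        | df["n_supporting_reads"].isna()
        | (df["tl_p75"] < 0) | (df["n_supporting_reads"] < 1)
    )
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +1 header, +1 one-based
        msg = f"{bad.sum()} malformed row(s) at file line(s) {lines}"
        if strict:
            raise CallFormatError(msg)
        warnings.warn(msg)
        df = df[~bad].reset_index(drop=True)
    return df


def save_calls(calls: pd.DataFrame, path) -> None:
    """Write a call table as TSV (canonical columns first, extras after)."""
    cols = [c for c in CALL_COLUMNS if c in calls.columns]
    cols += [c for c in calls.columns if c not in cols]
    calls[cols].to_csv(path, sep="\t", index=False)


def qc_filter(calls: pd.DataFrame, min_tl: float = MIN_CSTL_BP) -> pd.DataFrame:
    """Drop calls with TL below ``min_tl`` (strictly shorter), negative TVR
    length, or ambiguous arm mapping.  Idempotent."""
    keep = (
        (calls["tl_p75"] >= min_tl)
        & (calls["tvr_len"] >= 0)
        & ~calls["mapping_ambiguous"].astype(bool)
    )
    return calls[keep].reset_index(drop=True)


def group_p75(
    reads: pd.DataFrame,
    keys: Sequence[str] = ("sample_id", "arm", "allele"),
    value_col: str = "read_tl_bp",
) -> pd.DataFrame:
    """Per-group 75th percentile (linear interpolation between order
    statistics, the type-7 convention) plus group size, vectorized over
    all groups at once."""
    g = reads.groupby(list(keys), sort=True)
    codes = g.ngroup().to_numpy()
    v = reads[value_col].to_numpy(dtype=float)
    order = np.lexsort((v, codes))
    v_sorted = v[order]
    counts = np.bincount(codes)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    pos = starts + 0.75 * (counts - 1)
    lo = np.floor(pos).astype(np.int64)
    hi = np.ceil(pos).astype(np.int64)
    frac = pos - lo
    p75 = v_sorted[lo] * (1.0 - frac) + v_sorted[hi] * frac
    first = order[starts]  # one record per group, in group-code order
    out = reads.iloc[first][list(keys)].reset_index(drop=True)
    out["tl_p75"] = p75
    out["n_supporting_reads"] = counts
    return out


def _reads_to_calls(
    reads: pd.DataFrame,
    min_reads: int | Mapping[str, int],
    tier_by_sample: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Reduce a read-level table to per-allele calls: the 75th percentile
    of each cluster's read TLs, dropping clusters below the minimum
    supporting-read threshold."""
    calls = group_p75(reads).rename(columns={"allele": "allele_index"})
    if isinstance(min_reads, Mapping):
        if tier_by_sample is None:
            raise ValueError("per-tier min_reads requires tier_by_sample")
        thr = calls["sample_id"].map(tier_by_sample).map(min_reads)
        if thr.isna().any():
            missing = calls.loc[thr.isna(), "sample_id"].unique()[:5]
            raise ValueError(f"no coverage tier for sample(s) {list(missing)}")
    else:
        thr = int(min_reads)
    return calls[calls["n_supporting_reads"] >= thr].reset_index(drop=True)


def collapse_to_arm(
    calls: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    min_reads: int | Mapping[str, int] = 3,
    tier_by_sample: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Collapse QC-passed calls to one csTL per sample x arm.

    Accepts either an allele-call table (``tl_p75`` column) or a
    read-level table (``read_tl_bp`` column); read tables are first
    reduced to allele calls via the 75th-percentile rule subject to
    ``min_reads``.  The csTL is the arithmetic mean over allele estimates
    (single estimates used as-is); ``n_allele_estimates`` and total
    supporting reads are carried along.  Covariates from ``metadata``
    (keyed by ``sample_id``) are merged when provided.
    """
    if "read_tl_bp" in calls.columns:
        if tier_by_sample is None and metadata is not None \
                and "coverage_tier" in metadata.columns:
            tier_by_sample = dict(
                zip(metadata["sample_id"], metadata["coverage_tier"])
            )
        calls = _reads_to_calls(calls, min_reads, tier_by_sample)
    agg = {"cstl_bp": ("tl_p75", "mean"), "n_allele_estimates": ("tl_p75", "size")}
    if "n_supporting_reads" in calls.columns:
        agg["n_supporting_reads"] = ("n_supporting_reads", "sum")
    tab = (
        calls.groupby(["sample_id", "arm"], sort=True)
        .agg(**agg)
        .reset_index()
    )
    if metadata is not None:
        tab = tab.merge(metadata, on="sample_id", how="left")
    return tab


def resolve_duplicate_samples(
    calls: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Keep one sequencing run per individual when several exist.

    ``metadata`` needs columns ``sample_id, individual_id, platform`` (and
    optionally ``run_id``).  PacBio runs are preferred over ONT; among
    runs on the preferred technology the one with more arms with estimates
    wins; remaining ties break lexicographically by (platform, run_id).
    More than two runs per individual is unmodeled and raises.
    """
    meta = metadata.copy()
    if "run_id" not in meta.columns:
        meta["run_id"] = meta["sample_id"]
    counts = meta.groupby("individual_id")["sample_id"].nunique()
    if (counts > 2).any():
        bad = counts[counts > 2].index.tolist()
        raise ValueError(f"individual(s) with >2 runs: {bad}")

    arms_per_sample = calls.groupby("sample_id")["arm"].nunique()
    keep_samples: list[str] = []
    for _, grp in meta.groupby("individual_id"):
        if len(grp) == 1:
            keep_samples.append(grp["sample_id"].iloc[0])
            continue
        grp = grp.assign(
            is_pacbio=~grp["platform"].str.upper().str.contains("ONT"),
            n_arms=grp["sample_id"].map(arms_per_sample).fillna(0).astype(int),
        )
        grp = grp.sort_values(
            ["is_pacbio", "n_arms", "platform", "run_id"],
            ascending=[False, False, True, True],
        )
        keep_samples.append(grp["sample_id"].iloc[0])
    return calls[calls["sample_id"].isin(keep_samples)].reset_index(drop=True)


def exclude_arms(arm_table: pd.DataFrame, mode: str = "analysis") -> pd.DataFrame:
    """Drop arms that cannot be assigned telomeres unambiguously.

    mode "acrocentric_p": drop {13p, 14p, 15p, 21p, 22p}.
    mode "analysis": additionally drop the sex-chromosome arms, leaving
    the 39 autosomal arms.  Samples left with no arms are removed; their
    ids are recorded in ``result.attrs["dropped_samples"]``.
    """
    if mode == "acrocentric_p":
        drop: frozenset[str] = ACROCENTRIC_P
    elif mode == "analysis":
        drop = ACROCENTRIC_P | SEX_ARMS
    else:
        raise ValueError(f"unknown exclusion mode: {mode!r}")
    out = arm_table[~arm_table["arm"].isin(drop)]
    before = set(arm_table["sample_id"].unique())
    after = set(out["sample_id"].unique())
    dropped = sorted(before - after)
    if dropped:
        warnings.warn(
            f"{len(dropped)} sample(s) lost all arms after '{mode}' exclusion"
        )
    out = out.reset_index(drop=True)
    out.attrs["dropped_samples"] = dropped
    return out


def sample_summaries(
    arm_table: pd.DataFrame, reads: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-sample summaries: telomeric coverage (total supporting reads),
    number of arms with an estimate, mean TL, and shortest TL."""
    g = arm_table.groupby("sample_id")
    out = pd.DataFrame(
        {
            "n_arms_with_estimate": g["arm"].nunique(),
            "mean_tl": g["cstl_bp"].mean(),
            "shortest_tl": g["cstl_bp"].min(),
        }
    )
    if reads is not None:
        out["telomeric_coverage"] = reads.groupby("sample_id").size()
    elif "n_supporting_reads" in arm_table.columns:
        out["telomeric_coverage"] = g["n_supporting_reads"].sum()
    out["telomeric_coverage"] = (
        out.get("telomeric_coverage", pd.Series(index=out.index, dtype=float))
        .fillna(0).astype(int)
    )
    return out.reset_index()


def arm_call_rate(
    tables: Mapping[str, pd.DataFrame] | pd.DataFrame,
    arms: Iterable[str] = ARM_LABELS,
) -> pd.DataFrame:
    """Proportion of samples with a csTL estimate per arm, per group.

    ``tables`` is either a mapping group -> arm table or a single arm
    table (one group, "all").
    """
    if isinstance(tables, pd.DataFrame):
        tables = {"all": tables}
    arms = list(arms)
    rows = {}
    for group, tab in tables.items():
        n_samples = tab["sample_id"].nunique()
        if n_samples == 0:
            raise ValueError(f"group {group!r} has no samples")
        have = tab.groupby("arm")["sample_id"].nunique()
        rows[group] = [have.get(a, 0) / n_samples for a in arms]
    return pd.DataFrame(rows, index=pd.Index(arms, name="arm"))
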