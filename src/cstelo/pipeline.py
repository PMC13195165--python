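"""End-to-end orchestration: simulate -> aggregate -> downsample ->
adjust -> varcomp -> arm-assoc -> disease -> report.

Each stage reads its inputs from and writes its outputs to a run
directory as TSV (plus a JSON manifest), so stages can be re-run in
isolation; per-stage seeds are derived from the master seed by stable
hashing.  The report collates the variance-decomposition table and the
per-arm age-association table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arms import ANALYSIS_ARMS
from .config import SimConfig
from . import armassoc, batch, core, disease, downsample, lmm, simulate

log = logging.getLogger("cstelo")

STAGES = ("simulate", "aggregate", "downsample", "adjust", "varcomp",
          "arm_assoc", "disease", "report")

DEFAULT_FIXED = ("age", "sex", "ancestry", "smoking", "bmi", "batch")
DEFAULT_ADJUSTERS = ("sex", "ancestry", "smoking", "bmi", "batch")


def stage_seed(master_seed: int, stage: int | str) -> int:
    """Stable per-stage seed below 2^31 derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def config_hash(config: SimConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    version: str
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, outputs: Sequence[str], counts: Mapping[str, int],
            elapsed_s: float) -> None:
        self.stages.append(dict(
            name=name, outputs=list(outputs),
            record_counts=dict(counts), elapsed_s=round(elapsed_s, 3),
        ))

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False)
    return path.name


class PipelineError(RuntimeError):
    pass


def _require(outdir: Path, *names: str) -> None:
    missing = [n for n in names if not (outdir / n).exists()]
    if missing:
        raise PipelineError(
            f"missing upstream output(s): {missing}; run earlier stages first"
        )


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: SimConfig, outdir: Path) -> dict[str, int]:
    cohort = simulate.make_cohort(config)
    reads = simulate.emit_reads(cohort, config)
    calls = simulate.emit_calls(cohort, config, reads=reads)
    depth, avg = simulate.emit_depth_and_average_tl(cohort, config)
    summaries = simulate.truth_sample_summaries(cohort)
    flags = simulate.assign_disease(cohort, summaries)
    _write(cohort.individuals, outdir / "metadata.tsv")
    _write(reads, outdir / "reads.tsv")
    core.save_calls(calls, outdir / "calls.tsv")
    depth.reset_index().to_csv(outdir / "depth.tsv", sep="\t", index=False)
    _write(avg, outdir / "avg_tl.tsv")
    _write(flags, outdir / "disease_flags.tsv")
    cohort.arm_age_slopes.rename_axis("arm").reset_index().to_csv(
        outdir / "true_age_slopes.tsv", sep="\t", index=False)
    return {"individuals": len(cohort.individuals), "reads": len(reads),
            "calls": len(calls)}


def stage_aggregate(config: SimConfig, outdir: Path) -> dict[str, int]:
    _require(outdir, "calls.tsv", "metadata.tsv")
    calls = core.load_calls(outdir / "calls.tsv")
    meta = pd.read_csv(outdir / "metadata.tsv", sep="\t")
    calls = core.qc_filter(calls)
    tab = core.collapse_to_arm(calls, metadata=meta)
    tab = core.exclude_arms(tab, mode="analysis")
    summ = core.sample_summaries(tab)
    flags = pd.read_csv(outdir / "disease_flags.tsv", sep="\t")
    flags["cvd"] = disease.cvd_composite(flags)
    tab = tab.merge(flags, on="sample_id", how="left")
    _write(tab, outdir / "arm_table.tsv")
    _write(summ.merge(meta, on="sample_id").merge(flags, on="sample_id"),
           outdir / "sample_summaries.tsv")
    return {"arm_records": len(tab), "samples": tab["sample_id"].nunique()}


def stage_downsample(
    config: SimConfig, outdir: Path, seed: int,
    targets: Sequence[float] = (25, 20, 15, 10, 5),
    n_samples: int = 36, full_coverage: float = 30.0,
) -> dict[str, int]:
    """Coverage titration on a dedicated high-coverage sub-simulation
    (mirroring a reference panel of deeply sequenced samples)."""
    hc = dataclasses.replace(
        config, n_individuals=n_samples,
        coverage_model={"high": full_coverage, "mid": full_coverage},
        seed=stage_seed(seed, "downsample-cohort"),
    )
    cohort = simulate.make_cohort(hc)
    reads = simulate.emit_reads(cohort, hc)
    thr = max(config.min_reads_per_cluster.values())
    profile = downsample.run_titration(
        reads, targets, seed=stage_seed(seed, "downsample-thin"),
        min_reads=thr, current=full_coverage,
    )
    _write(profile, outdir / "downsample_profile.tsv")
    return {"titration_levels": len(profile), "hc_reads": len(reads)}


def stage_adjust(config: SimConfig, outdir: Path,
                 k_grid: Sequence[int] = range(0, 31)) -> dict[str, int]:
    _require(outdir, "depth.tsv", "avg_tl.tsv", "metadata.tsv", "arm_table.tsv")
    depth = pd.read_csv(outdir / "depth.tsv", sep="\t").set_index("sample_id")
    avg = pd.read_csv(outdir / "avg_tl.tsv", sep="\t")
    meta = pd.read_csv(outdir / "metadata.tsv", sep="\t")
    merged = avg.merge(meta[["sample_id", "age"]], on="sample_id")
    depth = depth.loc[merged["sample_id"]]
    pcs = batch.depth_pcs(depth)
    kmax = min(max(k_grid), pcs.scores.shape[1])
    adj = batch.select_k_and_adjust(
        merged["avg_tl_bp"], pcs, merged["age"], k_grid=range(0, kmax + 1))
    out = merged[["sample_id"]].assign(adjusted_tl=adj.adjusted, k_used=adj.k_used)
    _write(out, outdir / "adjusted_avg_tl.tsv")
    _write(adj.curve, outdir / "pc_k_selection.tsv")

    tab = pd.read_csv(outdir / "arm_table.tsv", sep="\t")
    tab = batch.residualize_on_batch(tab)
    _write(tab, outdir / "arm_table.tsv")
    return {"k_used": adj.k_used, "samples": len(out)}


def stage_varcomp(config: SimConfig, outdir: Path,
                  fixed: Sequence[str] = DEFAULT_FIXED,
                  batch_mode: str = "fixed") -> dict[str, int]:
    _require(outdir, "arm_table.tsv")
    tab = pd.read_csv(outdir / "arm_table.tsv", sep="\t")
    fixed = tuple(fixed)
    value_col = "cstl_bp"
    random = ("individual", "arm")
    if batch_mode == "residualize":
        fixed = tuple(f for f in fixed if f != "batch")
        if "cstl_resid" not in tab.columns:
            tab = batch.residualize_on_batch(tab)
        value_col = "cstl_resid"
    elif batch_mode == "random":
        fixed = tuple(f for f in fixed if f != "batch")
        random = ("individual", "arm", "batch")
    elif batch_mode != "fixed":
        raise PipelineError(f"unknown batch mode {batch_mode!r}")

    dec = lmm.variance_decomposition(tab, fixed, random=random,
                                     value_col=value_col)
    _write(dec.table, outdir / "varcomp.tsv")
    _write(dec.lrts, outdir / "varcomp_lrts.tsv")
    contribs = []
    for cov in fixed:
        r2, test = lmm.covariate_contribution(tab, cov, random=random,
                                              value_col=value_col)
        contribs.append(dict(covariate=cov, marginal_r2=r2, chi2=test.chi2,
                             df=test.df, pvalue=test.pvalue))
    _write(pd.DataFrame(contribs), outdir / "covariate_contributions.tsv")
    return {"components": len(dec.table), "covariates": len(contribs)}


def stage_arm_assoc(config: SimConfig, outdir: Path,
                    adjusters: Sequence[str] = DEFAULT_ADJUSTERS) -> dict[str, int]:
    _require(outdir, "arm_table.tsv")
    tab = pd.read_csv(outdir / "arm_table.tsv", sep="\t")
    age_assoc = armassoc.per_arm_ols(tab, "age", adjusters)
    _write(age_assoc, outdir / "arm_assoc_age.tsv")

    sign_rows = []
    for exposure, direction in (("age", "negative"), ("sex", "negative"),
                                ("smoking", "negative")):
        adj = tuple(a for a in DEFAULT_ADJUSTERS if a != exposure)
        if exposure != "age":
            adj = ("age",) + adj
        assoc = armassoc.per_arm_ols(tab, exposure, adj)
        st = armassoc.sign_binomial(assoc, direction)
        sign_rows.append(dict(
            exposure=exposure, direction=direction, n_arms=st.n_arms,
            n_in_direction=st.n_in_direction, p_hat=st.p_hat,
            ci_lower=st.ci_lower, pvalue=st.pvalue,
            pvalue_printed=st.pvalue_printed,
        ))
    _write(pd.DataFrame(sign_rows), outdir / "sign_tests.tsv")

    f, df1, df2, p, means = armassoc.arm_anova(tab)
    inter = lmm.age_by_arm_interaction(tab)
    r_mean_beta, p_mean_beta = armassoc.arm_vector_correlation(
        means, age_assoc.set_index("arm")["beta"].abs())
    summary = pd.DataFrame([
        dict(statistic="anova_F", value=f, detail=f"df=({df1},{df2}), p={p:.3g}"),
        dict(statistic="age_by_arm_chi2", value=inter.chi2,
             detail=f"df={inter.df}, p={inter.pvalue:.3g}"),
        dict(statistic="corr_mean_vs_abs_age_beta", value=r_mean_beta,
             detail=f"pearson, p={p_mean_beta:.3g}"),
    ])
    _write(summary, outdir / "arm_assoc_summary.tsv")
    _write(means.rename("mean_cstl_bp").rename_axis("arm").reset_index(),
           outdir / "arm_means.tsv")
    _write(inter.arm_slopes.rename_axis("arm").reset_index(),
           outdir / "arm_age_slopes.tsv")
    return {"arms": len(age_assoc), "sign_tests": len(sign_rows)}


def stage_disease(config: SimConfig, outdir: Path,
                  outcomes: Sequence[str] = ("cvd", "t2d"),
                  adjusters: Sequence[str] = ("age", *DEFAULT_ADJUSTERS)) -> dict[str, int]:
    _require(outdir, "sample_summaries.tsv")
    summ = pd.read_csv(outdir / "sample_summaries.tsv", sep="\t")
    if "cvd" not in summ.columns:
        summ["cvd"] = disease.cvd_composite(summ)
    metrics = disease.tl_metrics_with_exclusion(summ)
    rows = []
    for outcome in outcomes:
        # many-level batch dummies are unstable in logistic fits when an
        # outcome has few cases per batch; fall back to the biological set
        n_cases = int(metrics[outcome].astype(bool).sum())
        adj = tuple(adjusters)
        if "batch" in adj and n_cases < 5 * metrics["batch"].nunique():
            adj = tuple(a for a in adj if a != "batch")
        for metric in ("mean_tl_kb", "shortest_tl_kb"):
            r = disease.logistic_or(metrics, outcome, metric, adj)
            rows.append(dict(outcome=outcome, metric=metric,
                             odds_ratio=r.odds_ratio, ci_low=r.ci[0],
                             ci_high=r.ci[1], pvalue=r.pvalue,
                             n_cases=r.n_cases, n_controls=r.n_controls,
                             n_excluded=r.n_excluded))
    _write(pd.DataFrame(rows), outdir / "disease_assoc.tsv")
    return {"models": len(rows), "excluded": metrics.attrs["n_excluded"]}


def stage_report(config: SimConfig, outdir: Path) -> dict[str, int]:
    _require(outdir, "varcomp.tsv", "arm_assoc_age.tsv", "sign_tests.tsv")
    parts = []
    for name, title in (("varcomp.tsv", "Variance decomposition (PVE)"),
                        ("covariate_contributions.tsv", "Per-covariate marginal R2"),
                        ("sign_tests.tsv", "Directional consistency across arms"),
                        ("arm_assoc_summary.tsv", "Cross-arm statistics"),
                        ("disease_assoc.tsv", "Disease associations (OR per kb)")):
        f = outdir / name
        if f.exists():
            parts.append(f"## {title}\n" + pd.read_csv(f, sep="\t").to_string(index=False))
    (outdir / "report.txt").write_text("\n\n".join(parts) + "\n")
    return {"sections": len(parts)}


# ---------------------------------------------------------------------------


def run_pipeline(
    config: SimConfig | str | Path,
    outdir: str | Path,
    stages: Sequence[str] = STAGES,
    seed: int | None = None,
) -> RunManifest:
    """Run the listed stages in dependency order and write a manifest.

    ``config`` is a :class:`SimConfig` or a YAML path.  ``seed`` overrides
    the config's master seed.  A failing stage stops the run with the
    stage name in the raised error.
    """
    if not isinstance(config, SimConfig):
        config = SimConfig.from_yaml(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_used.yaml")

    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise PipelineError(f"unknown stage(s): {bad}")
    stages = [s for s in STAGES if s in stages]

    manifest = RunManifest(config_hash=config_hash(config),
                           master_seed=config.seed, version=__version__)
    runners = {
        "simulate": lambda: stage_simulate(config, outdir),
        "aggregate": lambda: stage_aggregate(config, outdir),
        "downsample": lambda: stage_downsample(config, outdir, config.seed),
        "adjust": lambda: stage_adjust(config, outdir),
        "varcomp": lambda: stage_varcomp(config, outdir),
        "arm_assoc": lambda: stage_arm_assoc(config, outdir),
        "disease": lambda: stage_disease(config, outdir),
        "report": lambda: stage_report(config, outdir),
    }
    before_files: set[str] = set(p.name for p in outdir.iterdir())
    for name in stages:
        t0 = time.time()
        log.info("stage %s: starting", name)
        try:
            counts = runners[name]()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        after = set(p.name for p in outdir.iterdir())
        manifest.add(name, sorted(after - before_files), counts,
                     time.time() - t0)
        before_files = after
        log.info("stage %s: done (%s)", name, counts)
    manifest.save(outdir / "manifest.json")
    return manifest
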