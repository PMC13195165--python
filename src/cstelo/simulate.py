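"""Synthetic cohort generator for chromosome-specific telomere analyses.

Generates per-haplotype true telomere lengths with a crossed
individual x arm variance structure, long-read style per-read calls with
Poisson telomeric coverage, a binned sequencing-depth matrix with latent
batch factors, short-read style average-TL estimates contaminated by those
factors, and logistic disease labels.

Every variance-bearing component (individual intercepts, arm deviations,
batch offsets, covariate effect columns, residuals) is rescaled to carry
*exactly* its configured fraction of total variance in the realized
cohort, so variance-partitioning estimates can be compared to the
configuration without Monte-Carlo slack in the generator itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arms import ANALYSIS_ARMS, ARM_LABELS
from .config import ConfigError, DiseaseParams, SimConfig

__all__ = [
    "Cohort",
    "make_cohort",
    "emit_reads",
    "emit_calls",
    "emit_depth_and_average_tl",
    "assign_disease",
    "truth_arm_table",
    "truth_sample_summaries",
]

# rng stream tags so stages can be re-run in isolation
_STREAM_COHORT, _STREAM_READS, _STREAM_CALLS, _STREAM_DEPTH, _STREAM_DISEASE = range(5)


def _rng(config_seed: int, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(config_seed), stream, extra])


@dataclass
class Cohort:
    """A simulated cohort: per-person metadata, per-site true TLs, and the
    realized per-arm age slopes (bp/year) used to generate them."""

    individuals: pd.DataFrame
    sites: pd.DataFrame
    arm_age_slopes: pd.Series
    config: SimConfig


def _scale_to_var(x: np.ndarray, target_var: float, mask: np.ndarray) -> np.ndarray:
    """Affinely rescale ``x`` so its masked subset has mean 0 and variance
    exactly ``target_var`` (population variance)."""
    if target_var <= 0:
        return np.zeros_like(x, dtype=float)
    sub = x[mask]
    sd = sub.std()
    if sd == 0:
        raise ConfigError(
            "cannot realize a positive variance fraction from a constant column"
        )
    return (x - sub.mean()) * (np.sqrt(target_var) / sd)


def make_cohort(config: SimConfig) -> Cohort:
    """Draw a cohort of diploid individuals with true per-site TLs.

    True TL at (person i, arm a, haplotype h) =
    grand mean + arm deviation + individual intercept + batch offset
    + covariate effects + arm-specific age slope x (age - mean age)
    + person-x-arm residual + haplotype deviation, floored at 1 bp.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_COHORT)
    n = config.n_individuals
    fr = config.variance_fractions
    total_var = config.total_sd**2

    # ---- individual-level covariates ----------------------------------
    batches = list(config.batch_design)
    bw = np.array([b.weight for b in batches], dtype=float)
    bidx = rng.choice(len(batches), size=n, p=bw / bw.sum())
    ancestry = np.empty(n, dtype=object)
    for k, b in enumerate(batches):
        m = bidx == k
        if not m.any():
            continue
        groups = list(b.ancestry_weights)
        pw = np.array([b.ancestry_weights[g] for g in groups], dtype=float)
        ancestry[m] = rng.choice(groups, size=m.sum(), p=pw / pw.sum())
    age = np.clip(
        rng.normal(config.age_mean, config.age_sd, n), *config.age_range
    )
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    smoking = np.where(rng.random(n) < config.ever_smoker_fraction, "ever", "never")
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 15.0, 60.0)

    individuals = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "ancestry": ancestry.astype(str),
            "smoking": smoking,
            "bmi": bmi,
            "batch": [batches[k].batch_id for k in bidx],
            "center": [batches[k].center for k in bidx],
            "platform": [batches[k].platform for k in bidx],
            "coverage_tier": [batches[k].coverage_tier for k in bidx],
        }
    )

    # ---- person x arm component grid (48 arms) ------------------------
    arms = np.array(ARM_LABELS)
    n_arm = len(arms)
    arm_of = np.tile(np.arange(n_arm), n)          # record -> arm index
    ind_of = np.repeat(np.arange(n), n_arm)        # record -> person index
    analysis_mask = np.isin(arms[arm_of], ANALYSIS_ARMS)

    profile = np.array([config.arm_mean_profile[a] for a in arms])
    grand = profile[np.isin(arms, ANALYSIS_ARMS)].mean()

    arm_dev = _scale_to_var(profile[arm_of], fr.get("arm", 0.0) * total_var,
                            analysis_mask)

    u_raw = rng.standard_normal(n)
    u = _scale_to_var(u_raw[ind_of], fr.get("individual", 0.0) * total_var,
                      analysis_mask)

    batch_raw = rng.standard_normal(len(batches))
    batch_eff = _scale_to_var(batch_raw[bidx][ind_of],
                              fr.get("batch", 0.0) * total_var, analysis_mask)

    anc_base = {"AFR": 0.0, "AMR": -1.0, "EUR": -1.0, "Other": -0.5}
    anc_eff = _scale_to_var(
        np.array([anc_base.get(a, 0.0) for a in ancestry])[ind_of],
        fr.get("ancestry", 0.0) * total_var, analysis_mask)

    sex_eff = _scale_to_var((sex == "male").astype(float)[ind_of] * -1.0,
                            fr.get("sex", 0.0) * total_var, analysis_mask)
    smoke_eff = _scale_to_var((smoking == "ever").astype(float)[ind_of] * -1.0,
                              fr.get("smoking", 0.0) * total_var, analysis_mask)
    bmi_eff = _scale_to_var(-bmi[ind_of], fr.get("bmi", 0.0) * total_var,
                            analysis_mask)

    # arm-coupled age slopes: |slope| increases with arm mean TL
    coupling = np.power(profile / grand, config.age_slope_coupling)
    age_c = age - age.mean()
    v_raw = -coupling[arm_of] * age_c[ind_of]
    age_eff = _scale_to_var(v_raw, fr.get("age", 0.0) * total_var, analysis_mask)
    if fr.get("age", 0.0) > 0:
        s0 = np.sqrt(fr["age"] * total_var) / v_raw[analysis_mask].std()
    else:
        s0 = 0.0
    arm_age_slopes = pd.Series(-s0 * coupling, index=arms, name="age_slope_bp_per_yr")

    resid = _scale_to_var(rng.standard_normal(n * n_arm),
                          config.residual_fraction * total_var, analysis_mask)

    cstl_true = (grand + arm_dev + u + batch_eff + anc_eff + sex_eff
                 + smoke_eff + bmi_eff + age_eff + resid)

    # ---- expand to 92 diploid sites -----------------------------------
    # autosomes: both haplotypes for every arm; sex arms: XX for females,
    # X + Y for males (92 sites per person either way)
    is_female = sex == "female"
    sex_arm_idx = {a: i for i, a in enumerate(arms)}
    keep = np.ones((n, n_arm, 2), dtype=bool)
    for a in ("Yp", "Yq"):
        keep[is_female, sex_arm_idx[a], :] = False
    for a in ("Xp", "Xq"):
        keep[~is_female, sex_arm_idx[a], 1] = False
    # females carry two X haplotypes, males one X (hap 0) and one Y (hap 1);
    # to keep 92 sites per male, Y arms use haplotype slot 0 only
    for a in ("Yp", "Yq"):
        keep[~is_female, sex_arm_idx[a], 1] = False

    hap = np.tile(np.array([0, 1]), n * n_arm)
    rec = np.repeat(np.arange(n * n_arm), 2)
    keep_flat = keep.reshape(n, n_arm, 2)[ind_of[rec], arm_of[rec], hap]

    allele_dev = rng.normal(0.0, config.allele_sd, rec.size)
    true_tl = np.maximum(cstl_true[rec] + allele_dev, 1.0)

    sites = pd.DataFrame(
        {
            "sample_id": individuals["sample_id"].to_numpy()[ind_of[rec]],
            "arm": arms[arm_of[rec]],
            "haplotype": hap,
            "true_tl": true_tl,
        }
    )[keep_flat].reset_index(drop=True)

    return Cohort(individuals, sites, arm_age_slopes, config)


def emit_reads(cohort: Cohort, config: SimConfig | None = None) -> pd.DataFrame:
    """Per-read telomere calls: Poisson(coverage rate) reads per site, each
    read's TL = true site TL + Gaussian noise (floored at 0)."""
    config = config or cohort.config
    rng = _rng(config.seed, _STREAM_READS)
    tier = cohort.individuals.set_index("sample_id")["coverage_tier"]
    rates = tier.map(config.coverage_model).to_numpy(dtype=float)
    rate_of_site = (
        cohort.sites["sample_id"].map(dict(zip(tier.index, rates))).to_numpy()
    )
    n_reads = rng.poisson(rate_of_site)
    rep = np.repeat(np.arange(len(cohort.sites)), n_reads)
    if rep.size == 0:
        return pd.DataFrame(
            columns=["sample_id", "arm", "allele", "read_tl_bp", "read_len_bp"]
        )
    tl = cohort.sites["true_tl"].to_numpy()[rep]
    if config.read_noise_sd > 0:
        tl = tl + rng.normal(0.0, config.read_noise_sd, rep.size)
    tl = np.maximum(tl, 0.0)
    anchor = np.maximum(rng.normal(15000.0, 4000.0, rep.size), 1000.0)
    return pd.DataFrame(
        {
            "sample_id": cohort.sites["sample_id"].to_numpy()[rep],
            "arm": cohort.sites["arm"].to_numpy()[rep],
            "allele": cohort.sites["haplotype"].to_numpy()[rep],
            "read_tl_bp": tl,
            "read_len_bp": tl + anchor,
        }
    )


def emit_calls(
    cohort: Cohort,
    config: SimConfig | None = None,
    reads: pd.DataFrame | None = None,
    tvr_artifact_rate: float = 0.005,
    ambiguous_rate: float = 0.01,
) -> pd.DataFrame:
    """Telogator2-style allele-cluster call table.

    Reduces reads to one call per sample x arm x allele cluster (75th
    percentile of read TLs, clusters below the tier's minimum supporting
    reads dropped) and decorates calls with a TVR length — occasionally
    negative, emulating boundary-detection artifacts — and an
    ambiguous-mapping flag.
    """
    config = config or cohort.config
    if reads is None:
        reads = emit_reads(cohort, config)
    rng = _rng(config.seed, _STREAM_CALLS)
    if reads.empty:
        return pd.DataFrame(
            columns=["sample_id", "arm", "allele_index", "tl_p75", "tvr_len",
                     "n_supporting_reads", "mapping_ambiguous"]
        )
    from .core import group_p75

    calls = group_p75(reads).rename(columns={"allele": "allele_index"})
    tier = cohort.individuals.set_index("sample_id")["coverage_tier"]
    min_reads = calls["sample_id"].map(tier).map(config.min_reads_per_cluster)
    calls = calls[calls["n_supporting_reads"] >= min_reads].reset_index(drop=True)

    m = len(calls)
    tvr = rng.normal(1500.0, 600.0, m).clip(min=0.0)
    artifact = rng.random(m) < tvr_artifact_rate
    tvr[artifact] = -np.abs(rng.normal(50.0, 30.0, artifact.sum()))
    calls["tvr_len"] = tvr
    from .arms import ACROCENTRIC_P
    amb_p = np.where(calls["arm"].isin(ACROCENTRIC_P), 0.25, ambiguous_rate)
    calls["mapping_ambiguous"] = rng.random(m) < amb_p
    return calls


def emit_depth_and_average_tl(
    cohort: Cohort,
    config: SimConfig | None = None,
    n_bins: int = 200,
    n_factors: int = 3,
    artifact_sd: float = 600.0,
    tl_noise_sd: float = 300.0,
    bin_noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binned sequencing-depth matrix with low-rank batch structure, and a
    short-read style average-TL estimate contaminated by the same latent
    batch factors.

    Setting ``artifact_sd`` to 0 yields an artifact-free average TL.
    """
    config = config or cohort.config
    rng = _rng(config.seed, _STREAM_DEPTH)
    ind = cohort.individuals
    n = len(ind)

    tier_score = np.where(ind["coverage_tier"] == "high", 1.0, -1.0)
    plat_score = np.where(ind["platform"].str.contains("Revio"), 1.0, -1.0)
    batch_codes = pd.Categorical(ind["batch"]).codes
    batch_score = rng.standard_normal(batch_codes.max() + 1)[batch_codes]
    scores = np.column_stack([tier_score, plat_score, batch_score])[:, :n_factors]
    scores = scores + rng.normal(0.0, 0.05, scores.shape)
    scores = (scores - scores.mean(0)) / scores.std(0)

    base_depth = np.where(ind["coverage_tier"] == "high", 30.0, 10.0)
    loadings = rng.standard_normal((n_factors, n_bins)) * 2.0
    depth = (base_depth[:, None] + scores @ loadings
             + rng.normal(0.0, bin_noise_sd, (n, n_bins)))
    depth_df = pd.DataFrame(
        depth, index=ind["sample_id"],
        columns=[f"bin_{j:04d}" for j in range(n_bins)],
    )

    true_mean = cohort.sites.groupby("sample_id")["true_tl"].mean()
    true_mean = true_mean.reindex(ind["sample_id"]).to_numpy()
    if artifact_sd > 0:
        w = rng.standard_normal(n_factors)
        artifact = scores @ w
        artifact = artifact / artifact.std() * artifact_sd
    else:
        artifact = np.zeros(n)
    avg_tl = true_mean + artifact + rng.normal(0.0, tl_noise_sd, n)
    avg_df = pd.DataFrame(
        {"sample_id": ind["sample_id"], "avg_tl_bp": avg_tl,
         "true_mean_tl_bp": true_mean}
    )
    return depth_df, avg_df


def assign_disease(
    cohort: Cohort,
    summaries: pd.DataFrame,
    disease_params: dict[str, DiseaseParams] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bernoulli disease labels from a logistic model on a per-person TL
    metric (kb scale): logit P = intercept + log(OR_per_kb) * metric_kb
    + optional covariate terms ('age', 'bmi', 'male', 'smoker')."""
    config = cohort.config
    disease_params = disease_params or config.disease_params
    rng = _rng(config.seed if seed is None else seed, _STREAM_DISEASE)
    df = cohort.individuals.merge(summaries, on="sample_id", how="inner")
    out = df[["sample_id"]].copy()
    for name, dp in disease_params.items():
        metric_kb = df[dp.metric].to_numpy(dtype=float) / 1000.0
        logit = dp.intercept + np.log(dp.or_per_kb) * metric_kb
        for cov, coef in dp.covariate_log_or.items():
            if cov == "male":
                x = (df["sex"] == "male").astype(float)
            elif cov == "smoker":
                x = (df["smoking"] == "ever").astype(float)
            else:
                x = df[cov].astype(float)
                x = x - x.mean()
            logit = logit + coef * x.to_numpy()
        p = 1.0 / (1.0 + np.exp(-logit))
        out[name] = rng.random(len(df)) < p
    return out


def truth_arm_table(cohort: Cohort) -> pd.DataFrame:
    """Noise-free person x arm csTL table (haplotype-averaged true TLs)
    merged with covariates — the generator's ground-truth counterpart of
    the aggregation pipeline's output."""
    tab = (
        cohort.sites.groupby(["sample_id", "arm"], sort=True)["true_tl"]
        .agg(cstl_bp="mean", n_allele_estimates="size")
        .reset_index()
    )
    return tab.merge(cohort.individuals, on="sample_id", how="left")


def truth_sample_summaries(cohort: Cohort, arms: tuple[str, ...] = ANALYSIS_ARMS) -> pd.DataFrame:
    """Per-person mean and shortest true csTL over the analysis arms."""
    tab = truth_arm_table(cohort)
    tab = tab[tab["arm"].isin(arms)]
    g = tab.groupby("sample_id")["cstl_bp"]
    return pd.DataFrame(
        {"mean_tl": g.mean(), "shortest_tl": g.min(), "n_arms_with_estimate": g.size()}
    ).reset_index()
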