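"""Disease association with mean and shortest telomere length.

Generates disease labels from a logistic model on the shortest TL
(OR 0.94 per kb), excludes 3-SD outliers, and refits adjusted logistic
models for the CVD composite (hypertension / ischemic heart disease /
heart failure) and type 2 diabetes.
"""

from cstelo import SimConfig, disease, simulate as sim

cfg = SimConfig(n_individuals=5000, seed=6)
cohort = sim.make_cohort(cfg)
summ = sim.truth_sample_summaries(cohort)
flags = sim.assign_disease(cohort, summ)
flags["cvd"] = disease.cvd_composite(flags)

df = summ.merge(flags, on="sample_id").merge(cohort.individuals, on="sample_id")
metrics = disease.tl_metrics_with_exclusion(df)
print(f"{metrics.attrs['n_excluded']} people excluded as 3-SD outliers")

for outcome in ("cvd", "t2d"):
    for metric in ("mean_tl_kb", "shortest_tl_kb"):
        r = disease.logistic_or(metrics, outcome, metric,
                                adjusters=("age", "sex", "smoking", "bmi"))
        print(f"{outcome:4s} ~ {metric:15s} OR = {r.odds_ratio:.2f} "
              f"[{r.ci[0]:.2f}, {r.ci[1]:.2f}], p = {r.pvalue:.2f} "
              f"({r.n_cases} cases)")
# OR < 1 means each extra kb of telomere lowers the odds of disease.
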