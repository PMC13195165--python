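"""Per-arm age associations, directional sign tests, and heterogeneity.

Runs one regression of csTL on age per arm, tests whether the direction
is consistent across the 39 arms with an exact binomial test, and asks
whether the age slope itself differs by arm (random-slope LRT, df = 2).
"""

from cstelo import SimConfig, armassoc, core, lmm, simulate as sim

cfg = SimConfig(n_individuals=500, seed=3)
cohort = sim.make_cohort(cfg)
tab = core.exclude_arms(
    core.collapse_to_arm(core.qc_filter(sim.emit_calls(cohort)),
                         metadata=cohort.individuals),
    mode="analysis")

assoc = armassoc.per_arm_ols(tab, "age", ("sex", "smoking", "bmi", "batch"))
print(assoc.head().round(3).to_string(index=False))

st = armassoc.sign_binomial(assoc, "negative")
print(f"\n{st.n_in_direction}/{st.n_arms} arms negative: "
      f"p-hat = {st.p_hat:.2f}, CI = [{st.ci_lower:.2f}, 1], "
      f"P = {st.pvalue_printed}")

f, df1, df2, p, means = armassoc.arm_anova(tab)
print(f"ANOVA of arm: F({df1}, {df2}) = {f:.1f}, p = {p:.2g}")
print("longest arms:", ", ".join(means.index[:3]),
      "| shortest arms:", ", ".join(means.index[-3:]))

inter = lmm.age_by_arm_interaction(tab)
print(f"age-by-arm interaction: chi2({inter.df}) = {inter.chi2:.1f}, "
      f"p = {inter.pvalue:.2g}")
r, pr = armassoc.arm_vector_correlation(
    means, inter.arm_slopes.abs().loc[means.index])
print(f"corr(arm mean csTL, |age slope|) = {r:.2f} (p = {pr:.2g})")
# A positive correlation means longer arms shorten faster with age.
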