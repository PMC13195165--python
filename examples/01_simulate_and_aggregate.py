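"""Simulate a cohort of long-read telomere calls and build the csTL table.

Generates per-allele calls for 300 people, applies QC (drop estimates
< 100 bp, negative TVR lengths, ambiguous arm mappings), collapses
alleles to one csTL per person x arm, excludes the acrocentric short
arms and sex chromosomes, and summarizes each person.
"""

from cstelo import SimConfig, core, simulate as sim

cfg = SimConfig(n_individuals=300, seed=1)
cohort = sim.make_cohort(cfg)
calls = sim.emit_calls(cohort)
print(f"{len(calls)} allele-cluster calls from {cfg.n_individuals} people")

kept = core.qc_filter(calls)
print(f"{len(calls) - len(kept)} calls removed by QC")

tab = core.collapse_to_arm(kept, metadata=cohort.individuals)
tab = core.exclude_arms(tab, mode="analysis")
print(f"arm table: {len(tab)} person x arm records, "
      f"{tab['arm'].nunique()} arms")

summ = core.sample_summaries(tab)
print(summ[["sample_id", "n_arms_with_estimate", "mean_tl",
            "shortest_tl"]].head().round(0).to_string(index=False))
# mean_tl is each person's average csTL across measured arms (bp);
# shortest_tl is their minimum - the candidate disease biomarker.
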