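"""Predict transcription-factor regulators of aging genes by enrichment.

For each region the positively age-correlated genes (top 200 by |r|) are
tested against every TF's annotated target set; TFs enriched in at least
three regions are kept, then filtered on >50% target coverage and checked
for age-correlated expression of the TF itself.
"""

from agescreen import (
    SimulationConfig,
    predict_tfs_per_region,
    rank_and_select_top,
    simulate_annotations,
    simulate_cohort,
    simulate_expression,
    spearman_age_correlation,
    target_coverage_filter,
    tf_age_profile_check,
    tf_consensus,
)

cfg = SimulationConfig(
    seed=31, n_samples=120, n_genes=800, n_sites=10,
    fraction_aging=0.05, n_tfs=3, targets_per_tf=60,
)
phenos = simulate_cohort(cfg)
expr, truth = simulate_expression(cfg, phenos)
anns = simulate_annotations(cfg, truth, padding=10)

tables = {r: spearman_age_correlation(expr[r], phenos[r], region=r) for r in cfg.regions}
per_region = {}
for r in cfg.regions:
    pos = sorted(tables[r].scored().index[tables[r].scored()["r"] > 0.3])
    top = rank_and_select_top(pos, tables[r], limit=200)
    per_region[r] = predict_tfs_per_region(top, anns["motif"], cfg.n_genes, alpha=0.01)
    print(f"{r}: {len(top)} input genes, enriched TFs: {list(per_region[r]['tf'])}")

tfs = tf_consensus(per_region, min_regions=3)
print(f"TFs enriched in >=3 regions: {tfs}")
for tf in tfs:
    inputs = sorted(truth.tf_targets[tf] | set(list(truth.shared)[:20]))
    frac, ok = target_coverage_filter(tf, inputs, anns["motif"])
    print(f"  {tf}: target coverage {frac:.0%} -> {'pass' if ok else 'fail'} (need >50%)")
profile = tf_age_profile_check(tfs, list(tables.values()), cutoff=0.3, min_regions=3)
print(profile.to_string(index=False))
# A credible regulator is enriched in most regions, covers most input genes,
# and is itself age-correlated -- the profile table shows per-region r.
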