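"""Cross-region consensus and methylation-site-to-gene mapping.

Screens four simulated brain regions, keeps features that pass the cutoff
with the same sign in at least three of them, then maps consensus
methylation sites to genes through +-2000 bp promoter windows and unions
the two gene sets.
"""

from agescreen import (
    SimulationConfig,
    consensus_across_regions,
    map_sites_to_genes,
    simulate_cohort,
    simulate_expression,
    simulate_genome,
    simulate_methylation,
    spearman_age_correlation,
    union_aging_genes,
)

cfg = SimulationConfig(
    seed=21, n_samples=120, n_genes=600, n_sites=300,
    fraction_aging=0.12, effect_r=0.6, shared_fraction=0.8,
    n_tfs=0, targets_per_tf=0,
)
phenos = simulate_cohort(cfg)
expr, truth = simulate_expression(cfg, phenos)
meth, meth_truth = simulate_methylation(cfg, phenos)

expr_tables = [spearman_age_correlation(expr[r], phenos[r], region=r) for r in cfg.regions]
meth_tables = [spearman_age_correlation(meth[r], phenos[r], region=r) for r in cfg.regions]

expr_cons = consensus_across_regions(expr_tables, 0.3, min_regions=3)
meth_cons = consensus_across_regions(meth_tables, 0.3, min_regions=3)
n_pos, n_neg, total = expr_cons.counts()
print(f"expression consensus  : {total} genes ({n_pos} pos + {n_neg} neg)")
print(f"methylation consensus : {len(meth_cons)} sites")

genome = simulate_genome(cfg, truth, meth_truth)
genes, skipped = map_sites_to_genes(meth_cons.features, genome["sites"], genome["tss"])
print(f"sites mapped to genes : {len(genes)} genes ({skipped} sites without position)")

rep = union_aging_genes(expr_cons.features, genes)
print(f"aging genes (union)   : {len(rep.union)}; overlap {len(rep.intersection)} "
      f"= {rep.pct_of_expression}% of the expression arm")
# The union is the aging gene list both arms contribute to; the truncated
# percentage quantifies how little the two molecular layers overlap.
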