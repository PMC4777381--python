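# agescreen

Aging changes the brain transcriptome and methylome gradually: some genes
drift up or down in expression over decades, and some CpG sites gain or
lose methylation.  `agescreen` identifies such **aging-related genes** the
way large multi-region brain cohort studies do — as features whose profile
correlates with donor age consistently across brain regions — and carries
the analysis through regulator prediction, module detection, network
assembly and disease-overlap testing.  It is aimed at computational
biologists who want this screening pipeline as a tested, scriptable library
rather than a collection of one-off analysis scripts.

## The method

For each feature *g* (gene expression or methylation beta value) and donor
ages *y*, compute Spearman's rank correlation *r<sub>g</sub>* = corr(rank
*x<sub>g</sub>*, rank *y*).  The selection cutoff *c* is calibrated by
permutation: shuffle the age vector over samples, recompute all feature
correlations, and record the per-iteration extremes (min *r*, max *r*);
after 1000 shuffles, *c* is the smallest symmetric threshold such that 95%
of iterations have their whole extreme range inside [−*c*, *c*].  The
Fisher transform *z* = ½·ln((1+*r*)/(1−*r*)) of the null extremes gives the
cutoff a z-score p-value.  A feature is a **consensus aging feature** when
|*r*| > *c* with a consistent sign in ≥ 3 of 4 regions; methylation sites
are mapped to genes through strand-aware ±2000 bp promoter windows, and the
two arms are unioned.

Downstream stages reuse one enrichment engine: the one-sided Fisher's exact
test of *x* annotated genes among *k* inputs, with *p* annotated among *n*
universe genes.  Two 2×2 constructions are supported — the construction
used in the source analysis, `[x, k−x; p−x, n−k]` (default, for
reproducibility), and the standard hypergeometric
`[x, k−x; p−x, n−k−(p−x)]` — see `docs/methods.md` for why they differ.
On top of it sit TF-regulator prediction (target-set enrichment, ≥3-region
consensus, strict >50% target-coverage filter, TF age-profile check),
co-expression modules (average-linkage clustering of the 1−r correlation
distance), a CSTP-style regulator network (top-k co-expressed neighbors →
regulator enrichment, with motif/literature/both evidence classes) and
aging–disease overlap plus shared-pathway calls.

A fully seeded synthetic-data generator emulates the study design
(multi-region cohorts, ages 15–101, planted monotone age effects with a
target |Spearman r|, TF-driven co-expression blocks, annotation files
consistent with the planted truth), so every stage is testable without any
download.

## Worked example

```bash
python examples/01_screen_and_calibrate.py
```

```
calibrated cutoff      : 0.322 (z-score p = 1.17e-02)
selected features      : 80 (40 pos / 40 neg)
planted features found : 80 of 80
false selections       : 0
```

One simulated 150-donor region with 800 genes, 10% of them carrying a
planted age effect of |r| ≈ 0.6.  The shuffle-calibrated cutoff (0.322) is
the 95% family-wise envelope of chance correlations for this matrix; every
planted feature exceeds it and nothing else does.  The remaining examples
(`examples/02` … `06`) walk through consensus + site mapping, TF
enrichment, modules, network assembly — e.g. a recovered degree histogram
`{1: 120}` meaning 120 targets with one regulator each — and disease
overlap.

The same stages are exposed as a CLI (`agescreen simulate | screen |
consensus | map-sites | enrich | tf-predict | modules | network | overlap |
run-all`); `agescreen run-all --config cfg.yaml --out-dir out/` runs the
whole pipeline from one YAML file and writes per-stage TSV/JSON plus a
provenance manifest.

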