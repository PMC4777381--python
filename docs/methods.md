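# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that affect reproducibility.

## Age-correlation screen

Each feature is scored by Spearman's correlation with donor age, computed
as Pearson correlation of average ranks (exact tie correction).  Samples
are aligned by id; features with missing values are scored on their
pairwise-complete samples with ranks recomputed on the shared support.
Features with fewer than 10 usable samples (configurable, floor 3) or zero
variance are flagged and excluded from selection and calibration.
Covariates (sex, batch) are deliberately not modeled: the screen is the
marginal rank correlation.

### Permutation calibration

The null model is "age assigned to random donors": each iteration applies
one permutation of the age vector to *all* features, preserving the
inter-feature correlation structure, and records the minimum and maximum
feature correlation.  After `n_iter` (default 1000) iterations the cutoff
is the smallest symmetric *c* with at least `coverage` (default 0.95) of
iterations entirely inside [−*c*, *c*] — equivalently the
⌈coverage·n_iter⌉-th order statistic of the per-iteration extreme
magnitude.  This is a family-wise quantity over the whole feature matrix:
a fraction `1 − coverage` of *matrices* under the null would produce any
feature beyond the cutoff.  An alternative reading — the quantile of the
pooled distribution of all shuffled correlations — is available via
`pooled=True`; it is necessarily no larger than the extreme-pair cutoff and
controls a per-feature rather than family-wise rate.

The magnitudes of the recorded extremes are Fisher-transformed
(z = atanh r, with |r| clipped to 1 − 1e−12 so degenerate perfect
correlations stay finite); their mean and standard deviation define the
z-score p-value of the cutoff, `P(Z > (atanh c − mean)/sd)` under a normal
approximation.  The z summary uses the recorded extremes, not the pooled
feature×iteration correlations, for memory reasons and because the
extremes are the quantities the calibration actually records.

Small-n exact mode: `exhaustive=True` enumerates all n! permutations
(n ≤ 8), which makes the n = 3 six-permutation null checkable by hand.
Calibration uses features with complete data across the shared samples;
features with missing entries are screened but excluded from the null.
Permutation sampling is `argsort` of seeded uniforms, so calibration is a
pure function of (matrix, ages, n_iter, seed).

### Selection and consensus

Selection is strict: r > c (positive) or r < −c (negative); a feature at
exactly the cutoff is excluded.  Consensus across regions is
direction-specific: a feature must pass with the same sign in at least
`min_regions` (default 3) regions; a feature positive in two regions and
negative in two supports neither direction.  When calibration is skipped
the operating cutoff defaults to 0.3.  When the pipeline calibrates per
region, the global cutoff is the maximum of the per-region cutoffs — the
conservative choice that keeps family-wise coverage in every region.

### Site-to-gene mapping

A methylation site maps to every gene whose promoter window contains the
site midpoint.  Windows are strand-aware and half-open around the TSS:
window (a, b) is [t+a, t+b) on '+' and [t−b, t−a) on '−'; the default
(−2000, +2000) is symmetric, so strand only matters for asymmetric windows.
Midpoint containment (rather than interval overlap) reflects the point-like
nature of methylation probes and is configurable by supplying wider site
intervals.  A precomputed site→gene table can bypass the window rule.

## Enrichment engine

For *k* input genes of which *x* carry an annotation, with *p* annotated
genes in a universe of *n*, the engine computes a one-sided ("greater")
Fisher's exact p-value.  Two table constructions are supported:

* **paper mode** (default): `[x, k−x; p−x, n−k]`.  This reproduces the
  construction used in the source analysis verbatim.  Note the fourth cell
  is *n−k*, not the hypergeometric remainder *n−k−(p−x)*: the implied
  population is inflated to *n+p−x*, which makes the test slightly
  conservative for x > 0.  It is kept as the default so published numbers
  can be reproduced, and the discrepancy is surfaced here rather than
  silently corrected.
* **standard mode**: `[x, k−x; p−x, n−k−(p−x)]`, the proper hypergeometric
  2×2.  Used wherever this package makes its own statistical claims
  (disease overlap, binding-site coverage).

Both are evaluated exactly via the hypergeometric survival function — the
same value `fisher.test(m, alternative="greater")` returns for the
corresponding table.  The universe size *n* is a required argument, never
defaulted, because enrichment conclusions are sensitive to it and the
appropriate universe (measured genes vs. genomic genes) is a study-level
decision.  No multiple-testing correction is applied by default (raw p
values are reported, matching the reproduced analysis); Benjamini–Hochberg
q-values are available via `bh_correct=True`.

TF prediction applies this engine to annotated target sets: inputs larger
than 200 genes are first reduced to the top 200 by |r| (ties broken by
feature id so the cut is deterministic); TFs enriched at α (default 0.01)
in ≥ 3 regions form the consensus, filtered on strict >50% target coverage
of the input list; finally each TF's own expression is checked for
|r| > 0.3 with a consistent sign in ≥ 3 regions.  Motif z-scores of
PWM-scanning tools have no counterpart here — the motif channel is an
annotation-set enrichment driven by Fisher p only, a documented
simplification.

## Co-expression modules

Gene-pair distance is 1 − Pearson r across all shared samples (range
[0, 2]).  Modules come from average-linkage hierarchical clustering with a
fixed-height cut (default 0.75, i.e. genes merging at average r > 0.25);
clusters below `min_size` (default 30) become label 0, "unassigned".
Labels are renumbered by decreasing size with ties broken by the smallest
member id, so the partition is invariant to input gene order.  This is a
deliberate, dependency-light replacement for soft-threshold/TOM-based
module detection: only the 1−r distance is specified by the reproduced
procedure, and no attempt is made to reproduce any particular published
module count, which is data-dependent.

## Regulator network

For each query gene: (1) take the k (default 200, mirroring the enrichment
input-size rule) genes with the highest *positive* Pearson correlation to
it — "similar expression profiles" is read as positive co-expression, with
an |r| option — then (2) test every candidate regulator's target set for
enrichment among those neighbors, separately for the motif and literature
collections.  Edges carry evidence `motif`, `literature` or `both`;
self-loops are dropped.  The summary reports targets-with-regulators, the
histogram of distinct regulators per target, edges and dual-evidence
edges; the identity Σ(multiplicity × count) = n_edges is asserted on every
build.  Only this two-step skeleton of co-expression-based regulator
recovery is implemented; the internals of the original tool it abstracts
are out of scope.

## Disease overlap

Gene ids are normalized (case-fold, version suffixes stripped) before set
operations.  Overlap significance uses the standard-mode test on the
membership 2×2 against a declared universe size.  Shared pathways: each
pathway is tested against either gene list independently and flagged when
both p-values are below α (default 0.01); the report is sorted by the worse
of the two p-values.  Disease gene lists are inputs — differential
expression meta-analysis and text-mining curation that would produce them
from raw data are out of scope, and the synthetic generator provides
structurally equivalent stand-ins.

## Synthetic-data generator

The generator emulates the study design the screen was built for: 4 brain
regions (CRBLM, FCTX, PONS, TCTX), 147 donors per region by default, ages
uniform on [15, 101] years.  Its defaults are study conditions, not tuning
knobs.

* **Planted age effects.**  A planted feature is a monotone function of the
  age rank — the normal scores Φ⁻¹((rank−½)/n) — plus Gaussian noise.  The
  model is monotone-in-rank rather than linear-in-years because the screen
  is rank-based, which makes the target correlation `effect_r` (default
  0.6) directly interpretable.  The noise scale for a requested `effect_r`
  has no closed form under this model and is solved by Monte-Carlo
  bisection (tolerance ±0.02, seeded, cached per (effect_r, n)); the
  Gaussian-copula closed form σ = √(1/ρ² − 1), ρ = 2 sin(π r/6) brackets
  the search.
* **Region sharing.**  A `shared_fraction` (default 0.8) core of planted
  features is common to all regions; the rest are region-private,
  emulating partial cross-region overlap.  Planted features split evenly
  into positive and negative directions.
* **TF blocks.**  Each simulated TF drives a block of `targets_per_tf`
  targets = TF profile + noise, sized so within-block correlation is
  `block_within_r` (default 0.9).  With `tf_age_effect=True` (default) TF
  profiles carry the age signal, like the age-correlated regulators the
  screen is meant to find — which necessarily correlates all blocks
  (~0.4) through the common age component.  `tf_age_effect=False` gives
  mutually independent block drivers, the regime in which exact
  network-recovery statements are meaningful.
* **Methylation.**  The same latent planted profiles are passed through a
  logistic link with per-site baseline offsets, yielding beta values in
  (0, 1).  The link is strictly monotone, so the planted Spearman structure
  — and the `effect_r` calibration — carries over exactly (logit-normal
  noise rather than literal Beta sampling, chosen to keep the planted
  correlation exact).
* **Annotations and toy genome.**  Motif/literature target sets are the
  true blocks plus `padding` false positives; pathways partition the
  planted aging genes plus filler; a reference aging list overlaps the
  truth at a configurable rate; disease lists share a configurable number
  of pathway cores with the truth.  The toy genome puts one TSS per gene
  on one chromosome (alternating strands), methylation sites inside their
  host promoters, and ChIP sites in the promoters of one TF's targets.

Everything is a pure function of the seeded configuration (seeds are
derived with a CRC-based stable hash, so runs are reproducible across
processes).

What the generator does **not** emulate: array probe design, batch or
cohort effects, non-monotone aging trajectories, realistic genome
geometry, or correlated annotation noise.  Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
declared generative model, not performance on real cohort data, where
effect sizes are smaller and confounding is real.

## Problem sizes and numerical choices

Recovery suites run at reduced but statistically meaningful sizes chosen as
the smallest scales at which the planted effects are clearly identifiable:
screen/consensus recovery uses 800 genes × 150 donors × 4 regions over 20
cohorts; calibration self-consistency uses 2000 null features × 147 donors
with 1000 calibration and 500 validation shuffles; network recovery uses
1500 genes with three 40-gene blocks and neighbor count k = 40 (equal to
the block size, so under independent drivers a neighbor list is exactly
one block).  Ties in ranks use average ranks everywhere; ties in orderings
(top-|r| cuts, neighbor lists) break lexicographically by feature id;
cluster labels renumber deterministically.  Correlations are clipped to
[−1, 1] against floating-point drift, and distance matrices are
symmetrized and clipped to [0, 2] before clustering.

## Known limitations

* The paper-mode contingency table is faithfully non-standard (see above);
  cross-mode comparisons should use standard mode.
* The z-score p-value of the cutoff relies on a normal approximation to
  Fisher-transformed extreme-value magnitudes, which is a descriptive
  summary rather than an exact tail probability.
* Module detection with a fixed-height cut is sensitive to the cut height
  in ways dynamic tree-cutting is not; the default 0.75 is appropriate for
  well-separated blocks.
* Regulator prediction inherits every bias of the annotation collections;
  an unannotated regulator cannot be found.
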