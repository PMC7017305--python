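# Methods

## Scope and model

`splicenet` re-implements, as a reusable desk-scale pipeline, a
splicing-machinery expression analysis over a 2×3 unbalanced factorial
design: central-nervous-system tissue (motor cortex, spinal cord) crossed
with disease state (control, and the two transcriptome-defined sporadic-ALS
subtypes SALS1 and SALS2). The stages are: probe-level normalization and
restriction to an a-priori splicing-gene panel; per-gene two-way ANOVA with
Benjamini–Hochberg FDR; fold-change screening over seven pairwise contrasts;
gene-set overrepresentation of the DEG lists; and first-order
protein–protein-interaction networks with hub-bottleneck /
nonhub-bottleneck classification.

## Normalization

Raw intensities v are thresholded at 1 and log2-transformed,
`x = log2(max(v, 1))`; each probe row is then baselined by subtracting its
across-sample median. An optional per-sample percentile shift (nearest-rank
dialect; e.g. 0.75 for a 75th-percentile shift) can be inserted between the
log transform and the baseline, but is off by default: the canonical path is
exactly the three explicit steps, and the unspecified vendor "normalized"
step is opt-in. Probes are collapsed to genes by the per-sample arithmetic
mean *after* normalization; the gene-level matrix feeds all downstream
statistics.

## Two-way ANOVA

For each gene, the linear model `y = μ + state + tissue + state×tissue + ε`
is fitted by least squares with sum-to-zero contrast coding. Because the
design is unbalanced (group sizes 18/13/10 in cortex, 17/13/10 in spinal
cord), per-effect sums of squares are marginal (Type III): the SS of an
effect is the increase in residual SS when that effect's columns are removed
from the full model. Sequential (Type I) SS are available by flag, in the
order state → tissue → interaction; the two agree exactly on balanced
designs, which the test suite asserts. All genes share one design matrix, so
residuals are computed by a single QR factorization per model and the fits
vectorize across genes; a per-gene statsmodels `anova_lm(typ=3)` fit is the
independent oracle in the tests.

Genes with numerically zero residual variance (residual SS below 1e-9 of the
gene's total centered SS) are flagged `degenerate` and report limiting
values — F = ∞, p = 0 when the effect SS is positive, F = 0, p = 1 when the
gene is entirely constant — rather than raising. BH adjustment is applied
per effect across genes (step-up, clipped at 1).

## DEG screening

For each of the seven contrasts, log2FC is the difference of group means on
the normalized (log2) scale; the linear fold-change magnitude is
`2**|log2FC|`. A gene passes a contrast when its relevant adjusted p is
strictly below α = 0.05 and its linear |FC| is strictly above 2. "Relevant"
is gated by contrast kind: disease-state contrasts require
`q_state < α or q_interaction < α`, tissue contrasts
`q_tissue < α or q_interaction < α`; a permissive `any` mode accepts any of
the three effects. Venn partitions of the per-effect significance sets and
the per-contrast DEG sets are exhaustive and disjoint by construction.

## Overrepresentation

Term enrichment uses the one-sided (greater) hypergeometric tail — Fisher's
exact overrepresentation test — with Bonferroni correction over the m terms
that have at least one member in the reference universe (terms with none are
skipped and excluded from m). The universe defaults to the filtered array
gene list supplied at run time. The per-term direction summary is a
majority-rule heuristic: "up" ("down") when more than half of the
overlapping DEGs share the sign of their log2FC, else "mixed".

## Network topology

The interactome (scored undirected edge table) is pre-filtered to the top
15% of edges by |score| — a top-count rule retaining exactly `ceil(0.15·m)`
edges, ties broken by stable input order; a nearest-rank value-threshold
mode is available. DEG seeds (duplicates collapsed by mean log2FC) are
expanded to their first-order network: seeds present in the interactome,
their direct neighbors, and every induced edge.

Degree and betweenness are computed on that assembled network. Betweenness
is unweighted and unnormalized (scores never act as path weights); each
unordered node pair contributes the fraction of its geodesics through a
node. The degree cutoff is `mean + 2·SD` of the network's degree
distribution, using the population SD (the node set is the whole population;
`--sd-sample` switches to N−1). Hub-bottlenecks have degree ≥ cutoff; the
comparison carries a 1e-9 absolute tolerance because the cutoff is a float
that can land a few ulp above an integer degree it equals in exact
arithmetic (the K1,4 star is the canonical case). Nonhub-bottlenecks have
degree < cutoff, positive betweenness with descending competition rank
≤ ceil(N/2) (ties share the better rank), and at least two hub-bottleneck
neighbors. The cutoff is frozen per network. Cross-condition comparison
reports shared/specific nodes per class with per-condition log2FC and an
opposite-trend flag.

## Synthetic data

The generator emulates the study's structure, not its biology: a 2×3
factorial with the cohort's unbalanced group sizes (18/13/10 cortex,
17/13/10 spinal cord, 81 samples), multi-probe genes, and i.i.d. Gaussian
noise on the log2 scale (default SD 0.5, a typical microarray residual
scale; baseline 8 log2 units). Planted effects are additive log2 shifts per
factorial cell, validated against their declared kind: tissue-main shifts
depend only on tissue, state-main only on state, and interaction patterns
must keep a nonzero residual after removing both unweighted margins (the
provided interaction helper plants a margin-free ±shift checkerboard).
Probes of one gene share its cell means plus independent noise, so
mean-collapsing is the matching estimator. The truth table flags genes
exactly by their planted effect kinds and records the expected log2FC of
each study contrast.

Interactomes grow by preferential attachment (connected, scale-free-like);
planted hubs receive extra uniformly chosen attachments until their degree
reaches the current mean + 2·SD, so they classify as hub-bottlenecks on the
unfiltered graph by construction. Edge scores are i.i.d. standard normal by
default (configurable), since only their ranks matter for filtering.
Annotation sets draw background terms uniformly (sizes 5–40); a planted term
keeps its member list verbatim.

The packaged synthetic study (`study_bundle`) uses a 400-gene panel with two
probes per gene; 25 genes 4-fold up in SALS1 and 25 4-fold down in SALS2
(pure state effects), 10 cortex-up tissue effects (1.5 log2), 15 margin-free
interactions (±1.5); a 400-node interactome (m = 2) with four planted hubs;
and 30 annotation terms whose planted term contains 80% of the planted
state-DE genes. All sub-seeds derive from one integer seed through a
`SeedSequence`; no global random state is touched.

What passing tests show — and do not show — about real data: the generator
has no probe-specific effects, heteroscedasticity, batch structure,
correlated genes, dye or spatial artifacts, and its interactome scores carry
no biological meaning. Recovery results therefore certify the statistical
machinery (calibration, ranking, classification contracts), not performance
on any real cohort.

## Numerical choices

- Degenerate-gene threshold: residual SS ≤ 1e-9 × max(total SS, 1e-12).
- Hub cutoff comparison tolerance: 1e-9 absolute.
- Betweenness rank: competition ranking (1 + number of strictly larger
  values), descending.
- Percentile dialect everywhere: nearest rank.
- Edge-filter ties: stable input order.
- Tables are TSV with 12 significant digits; GMT members are written sorted
  so serialization is canonical.

## Evaluation sizes

The calibration and recovery evaluations (`splicenet.evaluation`) use 2000
null genes for p-value calibration, 1000 genes with 100 planted 4-fold state
effects for sensitivity/FDR, and the 400-gene bundle end-to-end; these sizes
give sub-1% Monte-Carlo error on the calibration check while keeping the
whole evaluation under a few seconds on one core.

## Known limitations

- The vendor normalization internals beyond the three stated steps are not
  reproduced; the optional percentile shift is a stand-in.
- Which ANOVA effect gates which contrast, and whether BH was applied per
  effect or jointly, are interpretation choices (documented defaults:
  per-kind gating, per-effect BH).
- No moderated-variance (empirical Bayes) testing: plain per-gene ANOVA by
  design.
- The hub/nonhub definitions follow the stated wording; other formulations
  of "top 50% betweenness" exist and are not implemented beyond the
  documented rank rule.
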