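# Methods

This note documents the statistical procedures implemented in `apexdiff`,
the generative model behind its synthetic cohorts, the numerical
conventions chosen where several are in common use, and the limits of what
the test suite demonstrates.

## Setting

The package analyses 16S rRNA OTU count tables from an apical-periodontitis
(AP) cohort with four groups: healthy oral mucosa controls (HO, n = 9),
healthy tooth apices (HT, n = 10 teeth from 9 subjects, one subject
contributing two), untreated diseased teeth (NRCT, n = 23) and teeth with
failed root canal treatment (RCT, n = 8) — 50 samples in total. Diseased
teeth carry a radiographic lesion annotation classified as LSA (maximum
diameter ≥ 5 mm) or SSA (< 5 mm). The analysis unit is the sample; subject
ids are carried so either per-sample or per-subject conventions can be
applied where one subject contributes two teeth.

## Normalization and filtering

All between-sample comparisons run on counts **rarefied** to the cohort
minimum depth: each sample's column is replaced by a single multivariate
hypergeometric draw (subsampling reads without replacement), not an average
over draws, so downstream counts stay integral. The seed is an explicit
argument everywhere. Samples below the target depth are dropped with a
warning rather than erroring, because the default target is the minimum
over the cohort's own samples and the situation can only arise with
user-supplied depths.

Before differential testing, features present in fewer than
`ceil(0.10 × n_samples)` samples are removed. Taxon summarization
(phylum … genus) sums features sharing the full lineage prefix down to the
requested rank — keyed on the prefix, not the bare name, so homonymous
genera in different families stay separate; features lacking a name at the
rank are pooled into a single `unassigned` row carrying the common prefix
of its members. Aggregation conserves per-sample depth at every level.

## Diversity

Per sample: observed richness S_obs; Chao1
`S_obs + F1²/(2 F2)` with the bias-corrected fallback
`S_obs + F1(F1−1)/2` when F2 = 0 (F1, F2 = singleton and doubleton
counts — the F2 = 0 convention differs across implementations, so the
branch is pinned by tests); Shannon entropy `H = −Σ p_i ln p_i` in nats;
and the Gini–Simpson index `1 − Σ p_i²` (the common ecological default;
the dominance form Σp² and the inverse form are exposed as alternatives).
Group contrasts use the two-sided Wilcoxon rank-sum test on per-sample
values computed after rarefaction (a raw-count path exists for
completeness). Dominance curves report the cumulative read fraction of the
top-k OTUs, padded at 1 beyond the observed richness.

## Differential abundance

A feature is *significant* only when three criteria hold simultaneously:

1. **Storey q ≤ 0.05.** Two-sided Wilcoxon rank-sum p-values (exact by
   enumeration when n ≤ 12 without ties, else normal approximation with
   midrank tie correction and continuity correction) are converted to
   q-values with `π0 = min(1, #{p > λ}/(m(1−λ)))` at fixed λ = 0.5 — the
   single-λ estimator rather than the spline-over-grid variant: it is
   deterministic and adequate at this scale, and λ is a config knob.
   Forcing π0 = 1 reduces the procedure exactly to Benjamini–Hochberg,
   which the tests exploit as an independent oracle.
2. **Fold change ≥ 2** of group means on rarefied counts, with a +1
   pseudocount on both sides because zeros dominate these tables, oriented
   enriched/depleted (the group with the larger mean is the "high" group).
3. **Q3 floor.** The 75th percentile (linear interpolation between order
   statistics) of the *enriched* group's normalized counts must reach 10 at
   OTU level or 100 at genus level, discarding low-abundance candidates.

Paired contrasts (HT vs HO) match samples by subject, drop subjects
lacking a sample in either group, and use the two-sided signed-rank test
on per-subject differences (zeros dropped; all-zero input yields p = 1 with
a warning). Relabeling the two groups flips each record's direction but
leaves p, q, fold change and the significant set unchanged.

## Sample overlap

For every unordered pair of samples the present-feature sets split into
shared and unique parts. Richness fractions are taken over the union (the
shared slice is the Jaccard index); abundance fractions are, by default,
fractions of the two samples' **pooled reads** falling in shared /
x-unique / y-unique features, so each decomposition partitions to 1 —
matching the pie-chart geometry the statistic mimics, whose denominator is
not otherwise pinned down. A Bray–Curtis-like min-relative-abundance mode
is available (`mode="min"`, slices renormalized to a partition). Overlap
uses un-rarefied presence by default; note presence is depth-sensitive, so
a rarefied table can be passed when depths are very uneven. Pairs are
categorized O2O / T2T / O2T by body site (HO is oral; HT, NRCT and RCT are
tooth-derived), and category distributions are compared by rank-sum tests.

## Co-occurrence network

Pairwise Pearson correlations of significant-feature abundances across all
50 rarefied samples; two-sided p from `t = r√(n−2)/√(1−r²)` with n−2 df;
zero-variance features excluded with a warning. Upper-triangle p-values
are Holm-adjusted by default (BH optional — the adjustment behind the
published threshold is not specified, and Holm is the stricter default of
the usual correlation routines). An edge exists iff |r| > 0.6 and adjusted
p < 0.05; the absolute threshold keeps negative edges, which are reported
with their sign. Isolated nodes are retained; connected components are
labeled deterministically and k-core indices computed by iterative
minimum-degree peeling (the tests verify them against an exhaustive
pruning oracle on random graphs).

## Lesion subtypes

Lesion strings ("4×5 mm", mixed ×/x delimiters, optional "mm") parse into
two dimensions; the maximum classifies LSA (≥ 5 mm) vs SSA. NRCT samples
are clustered on genus-level relative abundances by agglomerative
clustering — Bray–Curtis dissimilarity with complete linkage as a standard
ecological default (both exposed: {braycurtis, euclidean, jaccard} ×
{complete, average, ward}), samples pre-sorted lexicographically so the
partition is deterministic. Concordance between the 2-cluster assignment
and the LSA/SSA labels is the best of the two cluster→label mappings
(hence ≥ 0.5); its p-value comes from uniform label permutations with the
+1/(n_perm+1) correction, computed through the hypergeometric sufficient
statistic (the count of first-label samples landing in cluster A fully
determines the shuffled accuracy), with Fisher's exact test as an
alternative. Recounting the published 23-row clinical table gives
19/23 ≈ 0.826 concordance, not the 0.885 printed alongside it; the
package freezes the recount, and the corresponding exact permutation
p-value is ≈ 1.7 × 10⁻³, not the < 10⁻⁶ printed for the irreproducible
accuracy — both divergences are pinned in the tests.

## Synthetic cohort model

No sequencing data is deposited for this design, so the generator emulates
the cohort's *marginal structure* and plants known effects for recovery
testing:

- **Rank abundance.** Each of 5,000 features gets a standard-normal score;
  a sample's expected composition weights unplanted features by
  `exp(σ_g · tilt)` where σ_g is the group's dominance parameter
  (HO 2.25, HT 2.40, NRCT 2.75, RCT 2.83 — calibrated so group-mean
  top-100 dominance fractions land near 72/75/83/85% and richness orders
  healthy > diseased).
- **Individuality.** The tilt is a mixture
  `√(1−ind)·z_cohort + √ind·η_sample` with `individuality = 0.9`: most of
  the dominance structure is sample-specific, reflecting the strong
  inter-individual variability of these communities. This matters
  statistically: with a fully cohort-shared tilt, every feature inherits a
  genuine group-level fold change from the dominance difference, and
  "false discovery" against the planted truth becomes ill-defined. With a
  mostly per-sample tilt, unplanted features are nearly exchangeable
  between groups at the single-feature level (per-feature AUC ≈ 0.5–0.6),
  while per-sample dominance and richness still separate the groups.
- **Paired subjects.** For a healthy subject's HO/HT samples the
  sample-specific tilt component shares a per-subject part with weight
  `paired_subject_effect` (default 0.3 — modest, since the study observed
  no strong excess overlap in same-subject pairs).
- **Planted effects.** Three disjoint sets with target relative shares
  ≈ 2×10⁻³ each (log-normal spread 0.5) where "high" and ×0.01 where
  suppressed: 49 features high in HO/HT and suppressed in both diseased
  groups; 40 features elevated in both NRCT **and** RCT and near-zero in
  healthy samples; 51 features present in subtype-B diseased teeth and in
  healthy samples but suppressed in subtype A. Extending the disease
  features to RCT, and giving RCT teeth a latent subtype in the NRCT
  proportion, makes NRCT-vs-RCT an expected-null contrast — matching the
  study's report of no significant OTUs there.
- **Noise and depths.** Per-sample compositions are Dirichlet perturbations
  of the expected profile (total concentration 300; ∞ disables the noise),
  and counts are multinomial at a depth uniform on [29,604, 68,088].
- **Labels.** The 23 NRCT samples split 9 A / 14 B; lesion strings are
  drawn to match the subtype (A large, B small) and flipped with
  probability 4/23, mirroring the discordance recounted from the published
  clinical table.

What the generator does **not** emulate: open-reference OTU-picking
artifacts (so absolute per-sample richness, ~300–600 here, is far below
the published 918–4,436 — the simulator targets orderings and dominance,
not those absolute values), phylogenetic structure among OTUs, chimeras,
and real taxon co-occurrence beyond the planted block structure. Passing
recovery tests therefore demonstrates correctness of the *procedures*
under a plausible abundance model, not performance on real amplicon data.

## Problem sizes and numerics

Tests and the acceptance script run the full 5,000-feature, 50-sample
cohort; type-I control is checked over 20 seeds of an effect-free,
equal-dominance design, calibration orderings over 5 seeds, and the
rarefaction distribution over 1,000 seeds of a toy community. Exact rank
tests switch to the normal approximation above n = 12 or in the presence
of ties (the approximation is verified within 0.02 of exact at
n_x = n_y = 5). Quantiles use linear interpolation. π0 falls back to 1/m
if no p-value exceeds λ. Ties in ranks get midranks with the matching
variance correction. Empirical FDR in recovery tests counts a call as
false only if the feature carries no planted effect at all; subtype
features carry a real partial NRCT-vs-HT shift by construction and are
excluded from both numerator and denominator.

## Known limitations

- Storey's π0 at a single λ can be anti-conservative when p-values are
  strongly non-uniform under the null (discrete rank-test p-values at small
  n); the three-criterion rule buffers this in practice.
- The pooled-reads overlap denominator weights deeper samples more; use the
  min mode (or rarefy first) when depths are very uneven.
- The concordance permutation test conditions on the cluster sizes; it does
  not account for the clustering having been fit to the same table.
- Correlation networks on compositional (rarefied) counts inherit the usual
  compositionality caveats; no CLR/SparCC-style correction is applied, by
  design, since the implemented procedure is the plain Pearson one.
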