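# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions, and the design choices where the published
description of the analysis left the design open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Overlap-enrichment statistics

### The hypergeometric layer and the two p-value conventions

Every enrichment question in the pipeline reduces to the overlap quadruple
(N, K, n, k): a background of N genes, K of which carry a property, a query
of n genes, and k genes in common. Under the null that the query is an
exchangeable draw, k ~ Hypergeometric(N, K, n), with expectation
E = nK/N and variance n(K/N)(1−K/N)(N−n)/(N−1).

`hypergeom_overlap_test` reports two probabilities:

* **`p` — the upper tail P(X ≥ k), inclusive.** This is the statistically
  meaningful enrichment test and the quantity used for ranking and
  multiple-testing adjustment. The inclusive convention is the only one
  coherent with enrichment tables whose O/E exceeds 1. It is computed by
  summing log-pmf terms (`gammaln`-based log-binomials) with `logsumexp`,
  so the result is exact to well below 1e-300; past float underflow the
  `log_p` field stays finite and the combined score is computed directly
  from it.
* **`p_point` — the point probability P(X = k), the "table convention".**
  Transcribing the published enrichment tables that this package reproduces
  and recomputing them revealed that every printed "hypergeometric
  distribution test" p value equals the *point* probability to all printed
  digits — the behaviour of spreadsheet-style `HYPGEOMDIST(k, n, K, N)`
  with `cumulative=FALSE` — and matches neither P(X ≥ k) nor P(X > k) to
  even one significant figure in some rows. The package therefore carries
  the point probability alongside the tail: `reproduce-tables` and the
  acceptance script verify the printed numbers under the convention that
  actually generated them, while analyses default to the upper tail. Both
  conventions agree on ranking in the deep-tail regime but can differ by a
  factor of ~2 in moderate tails; for fresh analyses use `p`.

The brute-force oracle in the test suite enumerates the pmf with exact
rational arithmetic (`math.comb` + `Fraction`) and confirms tail agreement
to 1e-10 relative for every population size up to 60; `scipy.stats.
hypergeom` serves as an independent cross-check at table scale.

### Fisher, chi-square, combined score, adjustment

Two-tailed Fisher's exact p sums, over the conditional support of a 2×2
table with fixed margins, the probabilities of all tables whose point
probability does not exceed the observed one (relative tie tolerance
1e-7, the mainstream convention). Degenerate margins return p = 1 with a
warning. Chi-square uses the closed-form 1-df Pearson statistic
N(|ad−bc| − correction)²/(r₁r₂c₁c₂) with optional Yates correction
(default off) and rejects tables with a zero expected cell in favour of
Fisher.

The **analytic combined score** is c = ln(p)·z with z = (k − E)/σ the
analytic z-score of the overlap count. The published formula pairs the
Fisher/hypergeometric significance with a "z-score deviation from the
expected rank" calibrated by rank permutation inside a large web platform;
that calibration is database-dependent and not reproducible from counts, so
this package substitutes the analytic z of the overlap itself and labels
the result accordingly. Natural log is used (the printed formula leaves the
base unstated). c is reported alongside p, never instead of it, and is
`None` when the null variance is zero.

Multiple-testing adjustment (Bonferroni, Benjamini–Hochberg step-up) is
delegated to `statsmodels.stats.multitest.multipletests` behind the
`adjust_pvalues` surface; hand-worked step-up examples in the tests pin the
conventions.

## MLME classification

The binary expression call is *strict median exceedance*: call(g, c) is
true iff value(g, c) > median over all cells of gene g (midpoint convention
for even counts). Ties at the median — including all-equal genes — are
not-expressed; "exceeded" is read strictly. Telomerase positivity is the
same call applied to TERT, the only expression rule the procedure defines.
The MLME decision is the conjunction: EPI ≥ 6, TE ≥ 7, PE ≥ 4 called
markers, all three of NANOG/POU5F1/SOX2, and TERT. The pluripotency trio is
normalised through a symbol-alias table (OCT4 → POU5F1), since the trio is
conventionally written both ways. The classifier is monotone (expressing an
additional marker can never revoke an MLME call) and equivariant under
gene/cell permutations; both are property-tested.

Panel cardinalities default to the 100/100/88 validation panels, with a
58-marker discovery preset (`DISCOVERY_PANEL_SIZES`, split 20/20/18 —
the published total is known but its per-lineage split is not) available
because the original marker lists live in supplementary material that the
package does not ship; panels are always explicit inputs.

**Derived DEG sets.** The source analysis uses MLME up/down-regulated gene
sets without stating their derivation. This package's documented choice: a
per-gene two-sided Wilcoxon rank-sum test (MLME vs non-MLME), BH adjustment
at α (default 0.05), direction by the difference of group medians with a
mean-difference fallback when the medians tie — necessary for sparse data,
where a marker expressed in under half of either group has median zero in
both. Under permuted labels the nominal rejection rate sits at or below α
(the discrete test is conservative) and the BH-adjusted sets are empty or
nearly so; both behaviours are tested.

## GPPA

Distance between an element and a gene is the gap between nearest interval
boundaries, 0 for overlapping intervals; association requires gap ≤ window
with the *inclusive* comparison, on the same chromosome, ignoring strand.
The default window is 10 kb. The gene anchor defaults to the whole gene
body; a strand-aware single-bp TSS anchor is provided because the published
association rule does not say which anchor was used. The implementation
(interval trees with an exact gap filter) is tested for equality against a
quadratic all-pairs scan on instances up to 2,000 intervals.

Signature-vs-network enrichment delegates to the hypergeometric layer with
N = genome gene count (default 63,677 — the genome-wide background the
reproduced tables state), K = |network|, n = |signature|,
k = |signature ∩ network|. The background dominates these p values, so it
is an explicit, logged parameter.

**Placement enrichment** of interval set A near interval set B (±window,
applied once, on the B side) supports two modes. Analytic: expected hits =
|A| × (merged, clipped bp coverage of B ± window)/genome length, with a
binomial upper-tail p — a point approximation of A that is adequate when A
intervals are small relative to the genome. Permutation: B re-placed
uniformly with lengths preserved, p = (1 + #{shuffles ≥ observed})/(1 +
shuffles). The permutation estimator is valid (super-uniform) but discrete;
the null-calibration test therefore bounds the anti-conservative one-sided
KS deviation tightly (< 0.05) and the two-sided KS distance loosely
(< 0.20), the slack carrying the discreteness of the count statistic.
Shuffling is uniform on a single sequence without exclusion zones;
masked/GC-aware shuffling is out of scope.

## Overlap accounting

Percentages are rounded **half-up** to 2 decimal places (and O/E to 2 dp)
to match the precision of the reproduced count tables; the rounding mode is
fixed because it affects fixture equality, and every emitted table carries
a self-audit that recomputes percents from counts. Stemness-matrix node
counts are (column sum of per-cancer driver-gene counts) × family count,
with 3 regulator families (HERV-H lncRNA, LTR7Y/B, LTR5_Hs/SVA_D) as the
default. Death attribution per cancer type is prevalence/100 × annual new
cases, capped at the type's annual deaths — the cap is stated by the
source; the pre-cap estimator is the only reading consistent with it.
Pearson correlation p values use the t transform on n−2 df with
Bonferroni adjustment for the declared number of tests.

### Known transcription inconsistency

In the transcribed stemness matrix, the silenced-gene column sums to 452,
giving 452 × 3 = 1,356 nodes, while the printed bold total is 1,365; the
activated column total (278 × 3 = 834) matches its print exactly.
`reproduce-tables` reports this as a consistency warning rather than an
error: `stemness_nodes` asserts only its own formula.

## Synthetic-data model

The generators exist to plant exactly the structure each downstream stage
detects; they do not model realistic scRNA-seq count distributions (no UMI
sampling, no library-size or batch effects). Passing tests therefore
demonstrate correctness of the *procedures* on data satisfying their
assumptions, not robustness to real-data artefacts.

**Expression.** Values are on a positive continuous scale (think log-ish
normalised expression, exponentiated):

* background entries are expressed with probability
  `background_on_fraction` (default 0.25) and otherwise exactly 0; an
  expressed entry is exp(ε), ε ~ N(0, `noise_sd`), then zeroed with
  probability `dropout_rate`;
* signal entries — the markers a planted cell expresses, its trio and TERT
  — are exp(`marker_effect` + ε) and are never dropped: the planted pattern
  is the construction, not a tendency;
* a planted MLME cell expresses a uniform number of markers per lineage
  between the criterion threshold (6/7/4) and the panel size; lineage-only
  cells express one panel only.

The sparse background is essential, not cosmetic: the median-exceedance
call on a *dense* continuous background is a fair coin per gene (any
continuous value exceeds its population median with probability 1/2), which
makes the ≥6/≥7/≥4 count criteria vacuous and floods the classifier with
false positives. With under-half background occupancy the per-gene median
is 0 and the call is exactly "non-zero" — the regime the marker-threshold
procedure implicitly assumes. Defaults (`marker_effect=3`, `noise_sd=1.0`,
`dropout_rate=0.1`, 135 planted MLME cells in a 1,000-cell cohort,
mirroring the reported 135-of-~800–1,000 selection) give sensitivity 1.0
and precision ≈0.98; in the noiseless limit (no noise, no dropout, no
background leak) recovery is exact by construction. Cohort size and planted
count are configurable.

**Genome fixtures.** Elements and genes are laid left-to-right with
randomized spacing on one or more synthetic chromosomes: each associated
gene starts at an independent gap in [0, window] downstream of its element
(genes may overlap one another), every other gene is placed > window from
all elements, so exactly round(fraction × n_genes) genes are associated, by
construction. Layouts that exceed the genome length raise an explicit
packing error.

**Gene-set libraries.** Planted sets sample members without replacement
with weight `enrichment_odds` on target genes; null sets sample uniformly.
With odds 1 the library is null: the nominal hypergeometric rejection rate
stays at or below α and mean O/E is 1 (tested at 2,000 sets).

All randomness in a generator call flows from its single integer seed
through one `numpy.random.default_rng` stream; identical configuration is
byte-identical output, which the pipeline test verifies end to end.

## Problem sizes

The test suite and acceptance script run at desk scale by design: cohorts
of 120–1,000 cells × 400–1,000 genes, interval sets up to 2,000 features
against quadratic oracles, 2,000-set null libraries, 200-dataset
permutation calibrations with 99 shuffles each. The enrichment-table
reproductions are closed-form in the printed counts and run in
milliseconds. Dataset-dependent counts of the original analyses (e.g. the
9,430 up-regulated genes or the 13,824 regulatory-sequence-associated
genes) are not recomputable from printed information and enter only as
fixture parameters, never as recomputed claims.

## Known limitations

* The generator's noise model is chosen for testability (planted structure
  exactly recoverable in the noiseless limit), not realism; effect sizes
  and noise levels for the real embryo data are not published, so the
  defaults are this package's own.
* The analytic placement model treats query intervals as points; for long
  A intervals the permutation mode is the honest estimate.
* The combined score's z is analytic, not rank-permutation calibrated, and
  is comparable across rows of one analysis but not with scores produced by
  external enrichment platforms.
* GREAT-style basal-plus-extension regulatory domains are intentionally not
  implemented; the ±10 kb boundary-gap rule is the contract.
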