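# Methods

This note documents the statistical procedures implemented in `progmod`,
the defaults and why they were chosen, the numerical conventions, and
what the synthetic-data experiments do and do not demonstrate.

## Survival kernels

**Log-rank test.** The unweighted (Mantel–Cox) two-sample statistic: at
each distinct pooled event time *t<sub>j</sub>* with *d<sub>j</sub>*
events among *n<sub>j</sub>* at risk (*n<sub>1j</sub>* in group A),
observed minus expected A-events *O − E = Σ(d<sub>1j</sub> −
d<sub>j</sub>n<sub>1j</sub>/n<sub>j</sub>)* is standardized by the
hypergeometric variance and referred to χ²₁. Subjects censored exactly at
an event time remain at risk for that time (events precede censoring).
p-values are two-sided; direction is carried by the hazard ratio, not the
test. A comparison with zero total events returns statistic 0, p = 1 and
a degenerate flag rather than an error, so genome-wide screens can skip
such genes gracefully.

**Hazard ratio.** The two-group HR is the MLE of exp(β) under the Cox
partial likelihood with a single binary covariate and **Efron** tie
handling, computed by bounded 1-D minimization (|β| ≤ 15, xatol 1e-8).
The one-dimensional solver exists because the genome-wide screen fits
tens of thousands of these models; a general Cox implementation would be
needless overhead, and the kernel is cross-checked against `lifelines`
in the test suite. The cruder Pike estimator
(O<sub>A</sub>/E<sub>A</sub>)/(O<sub>B</sub>/E<sub>B</sub>) is available
(`method="pike"`) and is attached to every log-rank result since it falls
out of the same risk table. A group with zero events yields HR = NaN
(non-identified), which screening treats as an exclusion flag.

**Kaplan–Meier.** Standard product-limit estimator; curves carry event
times, survival probabilities, at-risk counts and censoring marks, and
evaluate as right-continuous step functions.

**Multiple testing.** Benjamini–Hochberg step-up by default ("adjusted
p-value" defaults to FDR control, the field's usual reading); Bonferroni
is selectable. NaN p-values pass through without counting toward the
number of tests.

## Quartile survival screen

Per gene: the floor(n·f) samples with the smallest and largest expression
(f = 0.25 by default) form the low- and high-expression groups; ties at
the cut are resolved by stable sort order so the split is deterministic
and order-independent. The screen computes the log-rank p (adjusted
across all testable genes before thresholding), the HR of the
high-expression vs. low-expression group, and a fold change.

**Fold-change convention.** Fold change is the ratio of the
high-quartile group's median expression to the low-quartile group's, on
the linear scale (log2 input is exponentiated first, so the ratio equals
2^Δmedian). Because the two groups are quartiles of the *same* gene, this
ratio is ≥ 1 by construction: it measures separation magnitude, and the
direction of a call is carried entirely by the HR. A per-direction
literal variant (`fc_mode="literal"`: ratio > 2 for HIGH_POOR, inverse
ratio < 0.5 for LOW_POOR) is retained for comparison; with the oriented
ratio the two readings coincide.

Defaults — adjusted p < 0.001, fold change ≥ 2, quartile fraction 0.25 —
are the screening thresholds the pipeline was designed around; loosening
the p cutoff provably never shrinks the selected lists (tested).

Degenerate genes (constant expression, or zero events in either quartile
group) are flagged and excluded from calling, never imputed.

## Module construction

**Correlation graphs.** Pearson r across all samples; positive-mode
edges require r > 0.4 (strict), negative-mode edges r ≤ −0.4 (inclusive,
matching the convention that −0.4 is the largest admissible cross-pair
correlation). Zero-variance genes cannot carry a correlation and are
excluded with a flag.

**Clique extraction.** Iterated maximum clique: find the largest clique,
keep it if it has ≥ `min_cluster_size` genes (default 16, i.e. "more
than 15"), delete its vertices, repeat, stopping at `max_clusters`
(default 2) per direction. The search is an exact bitset branch-and-bound
up to a 500-node budget — comfortably above the few-hundred-gene lists a
genome-wide screen yields — with a greedy degeneracy heuristic and logged
warning beyond it. Equal-size ties are broken by the lexicographically
smallest gene-ID set: after the exact size is known, a depth-first search
that always extends with the smallest admissible gene returns the
canonical clique, making results independent of input order.

**Bi-clique pairing.** For every (high, low) cluster pair, the bipartite
graph of anticorrelated cross-pairs is searched for the maximal bi-clique
maximizing |A|·|B| (edge count), ties broken by the larger minimum side
and then lexicographically. Maximal bicliques are enumerated as maximal
cliques of the graph with both sides internally completed; at cluster
scale (tens of genes per side) this is exact and fast. Pairs with no
admissible bi-clique yield no module. Modules are ordered by total gene
count descending and labeled "module 1, 2, …", so module 1 is always the
largest. With two clusters per direction this yields up to four modules.

The min-size rule applies to the *pre-pairing clusters*; bi-clique
extraction may shrink the sides below it, which is why final modules can
legitimately have small sides.

## Scoring, stratification, validation

A sample's module score is median over high-side genes ÷ median over
low-side genes of that sample's expression (ratio mode), or the
difference of the two medians (difference mode). Ratio mode is the
definition for linear-scale intensities and is invariant under global
positive rescaling; difference mode is the same quantity in log units and
is the documented choice when `scale_hint="log"`, since ratios of
log-intensities are meaningless for non-positive values (ratio mode
raises a pointed error in that case). Genes absent from a cohort's
platform are dropped with a logged count; validation requires ≥ 3 matched
genes per side by default.

Stratification is by rank, not by value: median scheme assigns the top
⌊n/2⌋ samples to "high"; quartile scheme assigns top 25% = high, middle
50% = medium, bottom 25% = low. Rank-based cuts make labels invariant
under any strictly increasing transform of the scores and deterministic
under ties. (With three strata, "high score" denotes the top quartile —
the group with the poorest expected survival.) Validation compares the
extreme strata (log-rank + HR) and attaches KM curves for all strata.

Score–covariate association uses Kruskal–Wallis (≥ 3 levels) or
Mann–Whitney (2 levels), with BH-adjusted pairwise Mann–Whitney tests
when the omnibus is significant; nonparametric tests were chosen because
score distributions are skewed ratios. Both tests are configurable
nowhere — they are the robust default — but the raw summaries (n, median,
quartiles per level) are always reported so any downstream test can be
applied.

## TNBC differential expression

Welch (unequal-variance) t-tests per gene on log2 expression, BH FDR. A
gene is UP in TNBC when log2FC ≥ +0.5 with raw p < 0.05 and FDR < 0.05
(DOWN mirrored). The fold-change gate is read as a *floor* on |log2FC|: a
ceiling would discard exactly the strongest signals and cannot serve as a
DEG criterion. Cohort-level calls can be intersected across datasets
(consensus = same call everywhere), and module gene sets can be overlaid
on the calls to count TNBC-regulated module genes per side.

## Synthetic cohorts

`simulate()` draws, per sample, one standard-normal latent risk factor
per block pair. A block's activity mixes the shared factor (weight
α = √(cross_r/within_r)) with block-private noise, signed by direction;
genes add loading·activity to baseline-plus-noise with the loading set by
the closed form r = loading²/(loading² + σ²). This yields within-block
gene correlation ≈ within_r, high-vs-low cross-correlation ≈ −cross_r,
and mechanical anticorrelation from the shared factor. Event times are
exponential with hazard λ₀·exp(β·factor); censoring is exponential with
its rate calibrated by Gauss–Hermite quadrature so the expected censored
fraction hits the target. Covariates are Bernoulli/ordinal draws whose
logits shift with the factor, with marginals resembling a large breast
cancer cohort (≈16% TNBC, 76% ER+, half grade 3, 30% TP53-mutant, five
intrinsic subtypes with the basal-like/HER2-enriched logits rising with
risk).

Defaults define the study conditions used throughout the tests and the
acceptance script: n = 400 samples, 2000 genes, one 20-gene high-risk and
one 20-gene low-risk block, within_r = 0.7, cross_r = 0.5, β = 1 per
factor SD, baseline hazard 0.1 per time unit, censoring target 0.5
(moderate right-censoring typical of disease-free-survival follow-up),
gene noise SD 1 log2 unit around a baseline of 8 — the scale and spread
of normalized microarray intensities. `fixture_small()` is a 12-gene ×
24-sample deterministic variant with noise-free blocks (exact ±1
correlations) for hand-checkable unit tests.

**What the generator does not emulate:** probe-level noise and
probe→gene mapping loss, batch/platform effects, non-proportional
hazards, informative censoring, correlated null genes, and the long-tail
block-size heterogeneity of real co-expression networks. Passing the
planted-recovery tests therefore shows the pipeline is *correct and
well-calibrated under its own model assumptions* — not that it will
reach any particular operating point on a real cohort, where effect
sizes, correlation structure and censoring are less favorable and less
clean.

## Numerical conventions and degenerate inputs

- Missing expression values are rejected at load (optionally: drop the
  gene, logged) — silent imputation would contaminate the correlation
  graphs. Medians of even probe counts use the standard midpoint.
- All randomized components take explicit seeds; the full pipeline rerun
  from one seed produces byte-identical GMT/JSON artifacts (tested).
- Cox β is capped at |β| ≤ 15; a cap hit means the MLE is effectively
  infinite (separation) and downstream code treats the HR as unreliable.
- Constant score vectors cannot be stratified and raise; constant genes
  are flagged out of both screens.
- Disjoint expression/clinical sample sets raise at alignment; partial
  overlap restricts both tables to the intersection (idempotent).

## Problem sizes

The default test suite and the acceptance script run on simulated
cohorts of 200–2000 genes and 60–400 samples, with 5–10 replicate seeds
per stochastic claim and 1000–2000 genes per calibration claim — sizes
chosen so a full desk run completes in a few minutes while leaving
Monte-Carlo error well below the asserted margins.

## Known limitations

- The exact clique search is exponential in the worst case; the node
  budget with greedy fallback bounds runtime but sacrifices optimality on
  adversarial graphs (logged when it happens).
- The screen tests each gene marginally; correlated genes yield
  correlated tests, and BH control is nominal under positive dependence.
- The HR between score strata inherits the usual caveats of
  median-dichotomization (information loss, cohort-relative cutpoint).
- Cross-platform validation matches genes by identifier only; no
  ortholog/alias resolution is attempted.
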