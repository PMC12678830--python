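# Methods

This note documents the statistical model, the defaults and why they were
chosen, the numerical choices, and the limits of what the synthetic-data
tests demonstrate.

## Experimental design model

Nine conditions on primary neuron cultures, five replicates each by default:
an untreated control; bicuculline (Bic)-induced AP firing harvested at
0.5 h, 1 h, and 2 h; a short protocol (SP: 0.5 h Bic + 0.5 h intervention,
harvested at 1 h) with TTX or TTX+NMDA interventions; and a long protocol
(LP: 1 h Bic + 1 h intervention, harvested at 2 h) with TTX, TTX+NMDA, or
TBOA. The Bic-only endpoint of each protocol (1 h Bic for SP, 2 h Bic for
LP) is the reference against which interventions are measured, because an
intervention replaces the second half of the induction window.

Sixteen pair-wise contrasts are fitted by default: every treated condition
vs untreated (8), the within-protocol comparisons TTX vs Bic-endpoint,
TTX+NMDA vs Bic-endpoint, TTX+NMDA vs TTX for both protocols (6), and for
LP additionally TBOA vs Bic-endpoint and TBOA vs TTX (2). The TBOA-vs-TTX
contrast exists so that the "active effect of TBOA" column of the effect-
vector analysis is computable.

## Differential expression engine

A compact re-implementation of the standard NB count workflow; the contract
is the statistics, not bit-identity with any existing package.

* **Parameterization.** `var = mu + alpha * mu^2`; `alpha` is the
  reciprocal-size NB dispersion; `alpha = 0` is the Poisson limit.
* **Size factors.** Median-of-ratios against a pseudo-reference built from
  genes expressed in every sample, then centered so the geometric mean of
  the factors is 1. Centering makes the factors themselves scale-free; only
  ratios of factors are identified by the data.
* **Dispersion.** Per-gene method-of-moments on normalized counts, pooled
  over conditions with >= 2 replicates and weighted by residual degrees of
  freedom. The shot-noise term subtracted is `m * mean(1/sf)` per condition
  (the technical variance of a normalized count is `mu/sf`), which keeps the
  estimator consistent under unequal library sizes. Gene-wise estimates are
  moderated toward a robustly fitted trend `alpha(mu) = a0 + a1/mu` by
  geometric interpolation with weight 0.5 — enough pooling to stabilize the
  Wald test at 5 replicates without erasing genuine dispersion differences.
  Floor 1e-8 with a clamped flag.
* **Wald test.** Per gene and contrast, the group mean on the log scale is
  fitted by Newton iteration on the NB likelihood with the sample's size
  factor as exposure; the standard error comes from the expected information
  `sum mu/(1 + alpha*mu)`. `z = L2FC/SE`, two-sided normal p. Genes with
  zero counts in every sample of a comparison are not analysis-ready
  (status NA, all statistics absent); genes with a zero total on one side
  only are refitted with a 0.5 pseudocount on the group total and flagged.
* **Shrinkage.** Zero-centered normal prior on the L2FC; with the normal
  approximation to the likelihood the posterior mode is
  `L2FC * tau^2/(tau^2 + se^2)` — sign-preserving, magnitude-reducing,
  nearly identity for precise genes. The prior scale `tau` is estimated by
  moments (`tau^2 = mean(L2FC^2) - mean(se^2)`, floored at 1e-4) per
  contrast. This is an approximation to shrinkage with an adaptive normal
  prior, not a reproduction of any specific implementation.
* **Multiple testing.** Benjamini–Hochberg per contrast over analysis-ready
  genes only; NA rows are excluded from the number of tests.

Known deviation from the ideal: contrast statistics are only approximately
invariant under rescaling one sample's counts. Exact invariance is
impossible for honest NB inference — multiplying a sample's reads by c
genuinely reduces its relative shot noise and thus its likelihood weight.
Measured on well-expressed genes the effect is |delta L2FC| < 0.05 with
>= 99% concordant FDR calls.

## Activity classes

A one-way ANOVA per gene across the Bic series (untreated, 0.5, 1, 2 h) on
normalized counts, BH-corrected across genes, serves as the candidate
screen (default cutoff FDR < 0.01). Classification uses the three
Bic-vs-untreated contrasts plus normalized condition means:

* *transient*: significant (in the response direction) only at 0.5 h —
  excluded from protocol allocation; the rule is applied symmetrically to
  downregulated genes.
* *early*: condition-mean extremum at 1 h (vs 2 h) and significant at 1 h.
* *late*: extremum at 2 h and significant at 2 h; means within 1% relative
  of each other classify late, since the long protocol covers genes still
  high at 2 h.
* everything else: *unresponsive* (including the rare gene significant only
  at a non-extremum time under the default strict rule; the laxer
  significant-anywhere reading is available via
  `classify_activity(..., extremum_significance=False)`).

Early classes are assayed with SP, late classes with LP. Candidate genes
for embedding/concordance satisfy all three of: ANOVA FDR < 0.01, an
early/late class, and an L2FC assigned in every pair-wise comparison.

## Shut-off decomposition

For allocated genes, each component call uses the shrunken L2FC and FDR of
its defining contrast: down = (L2FC < 0, FDR < 0.05), up = (L2FC > 0,
FDR < 0.05), else ns. A gene is evaluable only if every contrast of its
protocol has statistics (the conservative all-comparisons rule). TBOA is
called only for LP genes. Percent metrics are `100*(2^L2FC - 1)` computed
from the shrunken L2FC of the respective contrast — percentages therefore
need not be multiplicatively consistent across components, since each
contrast is shrunk separately; a mean-ratio variant is available via
`use_shrunk=False`. The ranking sorts evaluable genes by total shut-off %
ascending (strongest reduction first), ties broken lexicographically by
gene id.

## Concordance

`s = a*b/sqrt(a^2+b^2)` with `s(0,0) = 0` by continuous extension. The
statistic is symmetric, positively homogeneous of degree 1, carries the
sign of `a*b`, and satisfies `|s| <= min(|a|, |b|)`. Effect vectors (LP,
late-induced candidates by default) are: passive = TTX vs Bic 2 h,
spillover = TBOA vs Bic 2 h, total = TTX+NMDA vs Bic 2 h, active =
TTX+NMDA vs TTX, active_tboa = TBOA vs TTX; shrunken L2FC by default
(switchable to MLE). Pearson correlations between columns use the standard
two-pass formula; zero-variance columns yield NA.

## Embeddings

* Condition-L2FC matrix: `log2((mean_c + 1)/(mean_untreated + 1))` on
  normalized condition means; pseudocount 1 bounds the distortion below 2%
  for means >= 100. Informative genes: across-condition SD (ddof = 1)
  strictly > 0.5.
* Clustering: Euclidean distance, complete linkage (scipy); ties merge
  lower-index clusters first, making leaf orders deterministic.
* PCA: `log2(x+1)` on normalized counts as the variance-stabilizing
  transform (a deliberate, documented approximation to a regularized-log
  transform — it affects variance-fraction values at low counts), top 500
  genes by variance, centered SVD.
* t-SNE: exact method (no Barnes–Hut), default seed 102 and perplexity 30;
  duplicate rows are permitted. Deterministic given the seed. The pipeline
  lowers perplexity automatically when candidates are scarce.

## Enrichment

Upper-tail hypergeometric p per gene set (`P(X >= x)`), BH across tested
sets; the background is the expressed-gene universe (genes with DE
statistics in every Bic-vs-untreated comparison). Gene sets come from GMT
files; sets with no background overlap are skipped. Multi-query comparison
uses a shared background with default cutoffs p <= 0.01, FDR <= 0.05.

## Synthetic-data generator

What it emulates: log-normal per-gene baselines (meanlog 5, sdlog 1 —
median expected count ~150, right-skewed like depth-normalized bulk
libraries); gamma-distributed NB dispersions (shape 2, mean 0.05, typical
for replicate cultures); per-sample library-size factors uniform on
[0.7, 1.3]; archetype kinetics with peak fold 8 — early (F, F, F/2) over
(0.5, 1, 2) h, late (1, F/2, F), transient (F, 1, 1), mirrored reciprocal
shapes for repressed genes — chosen so the max-at-time rules fire
unambiguously; and multiplicative intervention effects applied to the
allocated protocol's Bic endpoint.

Archetype fractions default to 70% unresponsive, 5% early-induced, 15%
late-induced, 4% transient, 3% + 3% repressed. Induced genes receive one of
six effect components: null (30%), passive-only 0.5x (15%), active-only
0.4x with TBOA 0.6x (25%), both (10%), passive shut-off boosted by NMDA
(0.5x passive, 1.7x active; 10%), and TTX-boosted/actively suppressed
(1.5x passive, 0.4x active; 10%). The headline multipliers (passive 0.5x,
active 0.4x) are the package's calibration choices for a clearly detectable
but realistic effect at five replicates; the two boosted components encode
the qualitative observation that passive and active dysregulation patterns
anticorrelate. Repressed archetypes carry a neutral effect triple — the
shut-off decomposition concerns induced genes.

Archetype and component labels are apportioned by largest remainder (quota)
and then shuffled, so realized category sizes are within one gene of
`fraction * n_genes` for every seed. One master seed feeds fixed
sub-streams for truth generation and count sampling; identical
configurations are bit-identical.

What it does **not** emulate: batch effects beyond library size, mean-
dispersion trends, correlated genes, isoforms/UMIs, single-cell structure,
or realistic effect-size distributions (the biology's true distributions
are unknown). Passing recovery tests therefore demonstrates that the
pipeline's inference machinery is correct and calibrated under its own
model assumptions — not that real-data sensitivity will match.

## Problem sizes and numerics

The default synthetic experiment is 10,000 genes x 45 samples; the full fit
(16 contrasts, classification, decomposition, concordance, PCA) takes a few
seconds. Acceptance reruns use 10,000 genes for recovery and 2,000 genes
for null calibration. Newton fits use 30 damped iterations (step clip 3 on
the log scale); dispersion floor 1e-8; BH via the standard step-up;
similarity at the origin defined as 0; dendrogram and ranking tie-breaks
are deterministic as described above.

## Known limitations

* The Wald test with moderated moment dispersions is slightly
  anti-conservative at very small replicate numbers (measured: ~6.7% of
  null p-values below 0.05 at n = 5 vs 5); BH selection remains controlled.
* The shrinkage prior is a single normal scale per contrast; genes with
  heavy-tailed true effects are shrunk more than an adaptive-tail prior
  would.
* Percent metrics inherit shrinkage: for genes with low counts the percent
  understates the point estimate of the reduction.
* The t-SNE perplexity default (30) is a conventional choice; embeddings
  are exploratory views, not inference.
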