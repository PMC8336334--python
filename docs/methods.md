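# Methods

`istmescore` trains immune and stromal gene signatures from bulk expression
data with survival annotations and scores arbitrary cohorts with them.  This
note documents the statistical model behind each stage, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Problem setting

Bulk tumor expression mixes malignant, immune and stromal (fibroblast,
vessel, matrix) transcription.  The package isolates the two
microenvironment programs as *latent factors*, keeps only genes carrying
prognosis-linked information about them, and summarizes any sample by two
rank-based enrichment scores — an immune score expected to be protective
(hazard ratio < 1 for overall survival) and a stromal score expected to be
adverse (HR > 1).  Cohort medians of the two scores define four
tumor-microenvironment (TME) subtypes: HH, HL, LH, LL, with the first
letter the immune level and the second the stromal level.

## Training pipeline

### 1. Normalization

Expression is normalized gene-wise: Z-score with the population
(n-denominator) standard deviation, then min–max to [0, 1].  The Z-score
puts genes on a common scale; the min–max step last guarantees the
non-negativity NMF requires.  Both are rank-preserving within a gene.
Constant genes cannot be scaled and are dropped with a logged count.  The
population/sample SD choice is arbitrary for every downstream rank-based
statistic; population SD is fixed for bit-reproducibility.  Z-scoring is
applied across samples within each gene (the orientation that makes genes
comparable between samples).

### 2. Latent factor extraction (KL-NMF)

The normalized matrix `V` (genes i × samples j) is factorized as
`V ≈ W H` with non-negative `W` (i × k) and `H` (k × j) by multiplicative
updates minimizing the generalized Kullback–Leibler divergence
`D(V‖WH)`.  These updates never increase the objective; entries are
floored at 1e-12 to avoid the zero-locking division-by-zero pathology.
Initialization is seeded uniform random scaled to match the data mean;
iteration stops at `max_iter` (default 2000) or when the relative objective
change drops below `tol` (default 1e-6).

Row `c` of `H` is the *eigenvalue* of factor `c`: a per-sample activity
profile.  Samples are assigned to the factor maximizing their `H` column,
genes to the factor maximizing their `W` row; argmax ties break toward the
lowest index so runs are reproducible.

The rank `k` defaults to 11 for real cohorts (the regime the signature
model was developed in).  `select_k` surveys candidate ranks by consensus
stability — for each candidate it runs several seeded fits, builds the
sample co-assignment matrix, and computes the cophenetic correlation of its
average-linkage dendrogram — because visual hierarchical-clustering
criteria do not automate cleanly.  For the synthetic default cohort the
end-to-end tests use `k = 7`: the generator plants 6 latent factors, and
one extra component absorbs the shared min–max baseline offset; at `k = 6`
the immune or stromal eigenvalue measurably mixes with a noise factor.

### 3. Immune/stromal cluster identification

For each factor, the top-100 genes by basis weight are tested for
over-representation against user-supplied immune and stromal reference
collections (hypergeometric upper tail, BH-adjusted across sets), and the
factor's eigenvalue is screened by univariate Cox regression (Breslow
ties).  The immune factor is the one with the smallest adjusted immune
enrichment P among factors with Cox P < 0.05 and HR < 1; the stromal
factor analogously with HR > 1.  Both direction constraints are hard
requirements: a "stromal" factor that predicts good outcome is a selection
failure, reported with the near-miss table.  The 0.05 screening threshold
is a declared default (`cox_alpha`), not a published constant.

### 4. Joint gene selection (ℓ2,1 multitask regression)

The two eigenvalues `Y = [H_immune; H_stromal]` (each row z-scored by
default) are regressed jointly on the full normalized matrix:

    min_W  Σ_t ‖W_tᵀX − Y_t‖²_F + ρ1‖W‖₂,₁ + ρL2‖W‖²_F ,
    ‖W‖₂,₁ = Σ_rows √(Σ_tasks w²)

The row-grouped ℓ2,1 penalty zeroes whole gene rows across both tasks, so
a gene is kept or discarded as a unit; the Frobenius ridge spreads weight
across correlated genes of the same module instead of letting one
representative absorb it.  The solver is FISTA: accelerated proximal
gradient on the smooth part with the exact row-wise group soft-threshold
as the prox, backtracking line search, `W = 0` start, and restart whenever
momentum would raise the objective, so the recorded cost trace is
non-increasing.  Selected genes are the nonzero rows (the prox produces
exact zeros; the `zero_tol = 1e-10` guard only absorbs float noise).

Defaults: `ρ1 = 0.15 · ρ1_max` where `ρ1_max = 2·max_row‖X Yᵀ‖₂` is the
smallest penalty that zeroes everything — an adaptive parameterization that
transfers across cohort scales — and `ρL2 = 10`.  The small ρ1 fraction
deliberately favors recall: false positives admitted here still face the
differential-expression filter, while a true gene discarded here is lost
for good.  `rho1_grid` provides a log-spaced candidate ladder up to
`ρ1_max` for users who want to tune.

### 5. Signature refinement (consensus clustering + moderated-t DGE)

The cohort is split into two consensus clusters: 20 seeded rank-2 KL-NMF
runs on the selected-gene submatrix, per-run labels by argmax of `H`,
co-assignment fractions averaged into a consensus matrix, final labels by
cutting the average-linkage tree of 1 − consensus at two groups.

Before factorization each gene row of the submatrix is replaced by its
within-gene ranks scaled to (0, 1].  This is a robustness device with a
specific failure mode behind it: expression marginals are heavy-tailed
(in the generator, log-normal activities), and rank-2 NMF on the raw
min–max values tends to isolate a small extreme-tail sample group
(≈ 170 / 30) instead of the dominant immune-versus-stromal contrast,
which starves the differential test of power on one axis.  Uniform
margins restore a balanced split.  The device is consistent with the
scoring stage's own rank-based philosophy and can be disabled
(`consensus_rank_normalize=False`).

The cluster with the higher mean immune eigenvalue becomes the *reference*
so that immune genes come out with positive logFC.  Differential
expression between the clusters uses a moderated t-statistic: per-gene
pooled variances are shrunk toward an inverse-gamma prior whose scale and
degrees of freedom are moment-matched on the log variances (trigamma
inversion by Newton), and the t degrees of freedom are inflated by the
prior df.  A plain Welch t is available (`dge_moderated=False`).
Benjamini–Hochberg adjustment runs across the selected genes — they are
the hypotheses under refinement.  The final signatures are the selected
genes with adjusted P < 0.05 split by logFC sign: positive → immune,
negative → stromal (sign-zero genes excluded; an empty side is an error).
A flag restores raw-P thresholding for users who read the P < 0.05 rule
unadjusted.

## Scoring pipeline

### ssGSEA scores

For each sample, genes are ranked by expression (ties averaged).  Walking
positions in decreasing rank order, signature genes contribute increments
proportional to `rank^α` (normalized over the signature), non-signature
genes uniform increments; the score is the sum over positions of the
running difference between the two cumulative distributions.  `α = 0.25`
by default (the convention of the single-sample enrichment literature).
Because only within-sample ranks enter, the score is invariant to any
strictly increasing per-sample transform — the property that makes it
portable across microarray and RNA-seq and tolerant of a few missing
signature genes.  Scoring requires at least 10 genes of each signature in
the matrix and warns below 50 % coverage.

Raw scores are min–max normalized across the scored cohort to [0, 1].
For deployment on new or single samples, `SSGSEAScorer` freezes the
training cohort's raw-score ranges and normalizes new samples against
them.

### TME subtypes and marker ratios

A sample is immune-high iff its normalized immune score strictly exceeds
the cohort median (values at the median class as low); likewise stromal.
The four labels are cohort-relative by design; frozen medians can be
applied cross-cohort via `TMESubtypeClassifier`.  `marker_ratio` computes
per-sample ratios of summed marker expressions on the raw/linear scale,
with bundled presets for the T-cell exhaustion ratio
(PDCD1 + CTLA4 + LAG3 + HAVCR2) / (CD28 + CD40LG) — HGNC symbols for
PD-1 and TIM-3 — and the angiopoietin balance ANGPT1 / ANGPT2.

## Survival machinery

Kaplan–Meier curves (product-limit, simultaneous decrement at ties),
k-sample log-rank tests (O−E/V statistic, χ² with groups−1 df), Cox
proportional-hazards fits with the Breslow tie approximation throughout
(chosen once for consistency; the tie method is otherwise a matter of
taste), and Harrell's concordance index with risk ties counted 0.5.
Cox covariates are standardized internally before the Newton fit and the
estimates mapped back — an exact reparametrization that prevents overflow
on heavy-tailed covariates; if Newton still fails, a BFGS fit is used.
Categorical covariates are dummy-coded against an explicit (or
lexicographically first) reference level.

## Synthetic data generator

`simulate_dataset` draws, per sample, latent activities for an immune
factor, a stromal factor and (default) 4 nuisance factors, all with
log-normal(0, 1) marginals.  The immune and stromal activities share a
Gaussian copula with correlation −0.5: the two programs compete for the
sampled tissue fraction, and the training procedure's binary consensus
split only carries both axes when they anti-correlate — cohorts with
independent programs are outside the model family the signature-splitting
step assumes.  Expression is `loading · activity` summed over the gene
modules (60 immune, 40 stromal, 50 per nuisance factor, defaults) plus
Gaussian noise (SD 0.5), then shifted globally to non-negative — shifting
rather than truncating keeps module–activity correlations exact.
Survival is exponential with log-hazard
`−0.8 · z(immune) + 0.8 · z(stromal)` on the standardized activities and
baseline hazard 0.1; a 30 % censoring fraction is realized by drawing
censoring flags and observing a uniform fraction of the event time.
`make_reference_sets` emits immune/stromal reference GMTs as the planted
modules with a stated fraction of genes swapped for random non-module
genes (default 10 % in tests), standing in for curated marker collections.

What the generator does **not** emulate: count noise (no mean–variance
relationship), batch structure beyond optional group shifts, correlated
gene-level noise within modules, non-proportional hazards, informative
censoring, and tumor-purity compositionality beyond the single
anti-correlation parameter.  Passing recovery tests therefore demonstrate
the pipeline's correctness under its own model assumptions, not
performance on real cohorts.

## Verification strategy and measured behavior

Every nontrivial statistic is tested against an independent oracle: the
ℓ2,1 solver against the per-task ridge closed form (ρ1 = 0) and the
zero-solution penalty bound; the proximal operator against an exact
cyclic coordinate-descent minimizer; KL-NMF monotonicity and exact
low-rank reconstruction; ssGSEA against a direct double-loop running sum
and hand-computed toy values; KM, C-index, log-rank and Cox against hand
product-limit arithmetic, all-pairs enumeration, a permutation null and a
grid-searched partial likelihood; BH against the brute-force step-up
definition.

End-to-end, on the default cohort (2000 × 200, seeded), the trained
signatures typically reach Jaccard ≈ 0.9 (immune) and ≈ 0.85 (stromal)
against the planted modules, and the scores reach Spearman ≥ 0.95 with
the latent activities.  The strict per-seed criterion (both Jaccards and
both correlations ≥ 0.8) holds in roughly 70 % of seeds.  The binding
constraint is structural: a single binary consensus split carries limited
information about the smaller (40-gene) axis at activity correlation
−0.5 and n = 200 — replacing the consensus labels with the oracle median
split on the true activity contrast does not rescue the failing seeds —
so borderline minority-axis genes (|t| ≈ 2) cannot be separated from the
chance-correlated false positives the selection step admits.  Larger
cohorts, stronger anti-correlation, or balanced module sizes all relax
the limit.

## Numerical choices and degenerate inputs

Argmax and rank ties break deterministically (lowest index,
lexicographic gene id, average ranks).  Duplicate gene rows collapse to
the max-mean row at load time (logged).  Samples missing survival data
are dropped, never imputed.  Constant genes, constant covariates,
event-free cohorts, empty gene-set overlaps, zero marker denominators and
empty signature sides all raise explicit errors (or warnings where a
degenerate answer exists, e.g. a flat KM curve).  All randomness flows
from integer seeds; two runs with identical config and inputs are
bit-identical.

## Limitations

The published 166-gene signature cannot be reproduced without the
original training cohorts; users who have it can supply it as a GMT and
score without training.  ρ1/ρL2 have no published values; the adaptive
defaults are tuned to the generator's regime and real cohorts may need
the grid helper.  Subtype labels are cohort-relative unless thresholds
are frozen.  Breslow ties are a (documented) choice, not a finding.
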