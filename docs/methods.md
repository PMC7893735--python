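# Methods

## Overview

`cfmeth` implements a tissue-informed cfDNA methylation classifier for
distinguishing malignant from benign breast lesions, together with a
synthetic-data generator that reproduces the statistical structure such a
study relies on. This note records the models, the defaults and why they
were chosen, and the limits of what the synthetic experiments demonstrate.

## The genome model

The simulated genome is a set of chromosomes carrying a CpG site process
with three density regimes: ordinary "dense" blocks (default 0.03–0.045
CpGs/bp), CpG deserts (0.0005/bp, ~30% of the genome), and CpG islands
(background × 5–6, ~1 kb, placed at gene promoters with probability 0.6).
Deserts are essential, not decorative: gap-based candidate segmentation
(max gap 500 bp) only yields sub-chromosome regions if real gaps exist.
Sites live on the even-position grid so the 2 bp dinucleotide footprint
never overlaps. A periodic promoter/gene/intergenic layout (1 kb / 5 kb /
4 kb) classifies every site and window; windowed GC is synthesized as an
increasing function of CpG rate, matching the empirical coupling of the two
axes. All coordinates are 0-based, half-open (BED convention).

Two genome scales are used. `build_genome()` defaults to 2 × 5 Mb for
genome-level statistics. Cohort studies default to `COHORT_GENOME`
(2 × 150 kb): with the standard 20,000 methylation-called fragments per
plasma sample this gives ≈ 11× depth, the depth regime of a real plasma
WGBS study, so per-DMR fragment counts per sample are realistic. The small
genome should be read as the marker-bearing excerpt of a genome, which is
why planted DMRs occupy a larger fraction of it (~20%) than DMRs occupy a
full genome.

## Tissue methylomes and planted DMRs

Baseline methylation is context-determined and identical in both groups:
islands 0.15, promoters 0.55, gene bodies/intergenic 0.85. Hypo-DMRs
(default 16, signed delta −0.5) are planted on CpG-sparse candidate runs;
hyper-DMRs (default 4, +0.4) on the island cores of the densest runs —
flanks of an island are already methylated and cannot gain, so applying the
gain to the island windows only keeps means inside [0, 1]. Means pushed
outside [0, 1] by explicit user-specified plantings are clamped with a
warning. Per-CpG betas are Beta(mc, (1−m)c) draws with concentration c = 30
(per-sample, per-CpG s.d. ≈ 0.08 at m = 0.5), plus a small per-sample
global shift (s.d. 0.01) for biological offset. Defaults of 9 malignant vs
10 benign reference samples match the scale of tissue panels feasible in a
single-center study.

## Fragment length models

Each origin has a discretized length distribution on [30, 499] bp: a
left-skewed mononucleosomal peak (skew-normal, numerically anchored so its
mode is exact), a sharp spike at the mode (weight 0.06–0.10, the
well-protected chromatosome length), and a small di-nucleosomal satellite.
Non-tumor: mode 167 bp, scale 20; tumor: mode 145 bp, scale 18. The sharp
component makes the histogram mode identifiable at n = 10⁵ (the modal bin
exceeds its neighbours by ~0.6% of total mass, ≫ sampling noise). A
consequence worth stating explicitly: the 90–150 bp size-selection window
captures ~18% of non-tumor but ~80% of tumor fragments, multiplying the
effective tumor fraction ≈ 4× before any likelihood is computed. That
enrichment is the mechanism size selection exists for, and it carries much
of the end-to-end signal.

## Plasma samples and cohorts

A plasma sample with tumor fraction φ draws each fragment's origin
Bernoulli(φ), its length from the origin's model, and its start from
windows weighted exp(−w·z) with w = 0.5 (doubled in promoter windows),
z the window CpG-density z-score — a minimal mechanism reproducing the
observed coverage loss in CpG-dense/promoter regions without modelling
nuclease biology. Each covered CpG call is Bernoulli(origin-group mean
beta) flipped with probability 0.01 (conversion error).

Cohorts default to 77 malignant vs 77 benign (discovery) and 24 vs 25
(validation). Malignant tumor fractions are Gamma(shape 3) with
stage-conditional means 0.005 / 0.01 / 0.02 / 0.04 for DCIS / I / II / III
— low-burden early disease, chosen once as plausible; only their ordering
is load-bearing for the stage tests. Stage mix 6/40/34/20%. Benign samples
carry φ = 0. Imaging scores are ordinal 1–5 discretizations of a latent
normal shifted by ~1.2 s.d. for malignancy, giving standalone AUC ≈ 0.8 —
deliberately informative but imperfect, so the combination question is
non-trivial. BI-RADS subcategory follows the mean imaging latent and is not
fed to the models (it would be collinear with its two parents).

## DMR calling

Rank-based two-sample testing (Mann–Whitney; Welch t behind a flag) on
per-sample region means, BH across candidate regions only — the region is
the unit of inference throughout. Defaults min_cpgs 4, max gap 500 bp,
|Δβ| ≥ 0.2, q ≤ 0.05. Equal p-values are ordered by larger |Δ| first so
output is deterministic. Constant-vs-constant comparisons short-circuit to
p = 1. With 19 samples the minimal exact Mann–Whitney p (~1e-5) is small
enough to survive BH across the ~50–60 candidate regions of the cohort
genome.

## Origin inference

The reference panel stores per-DMR, per-CpG group-mean methylation
probabilities clamped to [ε, 1−ε], ε = 0.01: the clamp keeps every
log-likelihood finite and caps the per-CpG evidence at ln(99) ≈ 4.6 nats.
Fragment likelihoods are independent-Bernoulli products over the ≥ 3 CpG
calls inside the DMR (min_cpgs_per_fragment = 3 — joint patterns, not
single CpGs, are what separate the origins). Classification is hard
thresholding of the log-likelihood ratio at ± ln 2 with an ambiguous band
in between; an exhaustive-enumeration oracle over all 2^k patterns (k ≤ 5)
checks the implementation exactly. The malignant ratio is the classified
count ratio; a posterior-weighted mixture estimate (mean sigmoid(llr)) is
available behind `RatioConfig(estimator="posterior")`. Ratios need ≥ 5
classified fragments, else the entry is missing; DMRs missing in > 50% of a
training cohort are dropped, remaining gaps are imputed with the per-DMR
benign median. Held-out cohorts are imputed with the *discovery* medians
and never drop columns, so refit models always find their features.

## Diagnostic models

Markers are the top 10 hypo-DMRs by single-marker AUC (ties by rank-test p,
then id) — a direct, threshold-free criterion. The cfMeth score is the
out-of-fold probability of a 500-tree random forest under stratified
10-fold CV (stock hyperparameters; the contribution is the feature
construction, not forest tuning); a refit on all discovery data scores
validation. The combined model standardizes [cfMeth, mammography,
ultrasound] and fits L2 logistic regression with the penalty chosen by
internal stratified 5-fold CV over a log-spaced grid; discovery combined
scores are produced out-of-fold (nested CV) so cutoff selection never sees
in-sample predictions — the leakage-safe reading of an otherwise open
design choice. The operating threshold is the largest score with discovery
FNR strictly below 2% (the bound is strict by definition). AUC CIs use
stratified nonparametric bootstrap (2000 resamples, percentile). Stage
association uses Kendall's tau-b on DCIS/I/II/III as 0–3; DCIS is reported
as its own stage in per-stage detection.

## Numerical and degeneracy choices

Histogram-mode ties break toward the smaller length; fragment-to-DMR
assignment is by CpG containment (interval overlap without a CpG carries no
evidence) with majority/leftmost tie rules; filtering keeps length
< 500 bp strictly; constant model features are dropped with a warning;
a constant score vector has stage trend 0 by convention; seeds propagate
through `numpy.random.SeedSequence` spawning so every artifact is
bit-reproducible per (config, seed).

## Problem sizes

Default test and acceptance workloads: 2 × 150 kb genome, ~11k CpGs, 19
tissue methylomes, 154 + 49 plasma samples × 20k fragments, 2000 bootstrap
resamples; a full simulate-and-analyze study runs in well under a minute,
and the multi-seed suites stay within ordinary desk budgets.

## What passing tests do and do not show

The generator reproduces the *mechanisms* — fragment-size contrast and its
enrichment under size selection, density-dependent coverage depletion,
hypo/hyper density asymmetry, stage-graded tumor burden, imperfect imaging
— but not the messiness of real plasma: no inter-individual benign
baseline variation beyond counting noise, no other contributing tissues,
no CNV/SNV structure, no batch or age effects, two-component mixtures
only. Recovery and AUC results on synthetic cohorts therefore demonstrate
internal consistency and statistical sanity of the pipeline, not clinical
performance; the headline clinical numbers of any real study require its
patient data. Real-cohort DMR counts (tens of thousands) and specific
marker gene identities are likewise out of scope at desk scale.
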