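# Methods

This note documents the statistical model behind each component, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that make runs
reproducible.

## Study design assumed

A panel of `2k (+ extra)` inbred parent lines, `k` F1 hybrids (one per
parent pair, parent1 being the cultivated-type parent by convention), two
ordered developmental stages (default CE = cell expansion, OR =
orange-red), and `r` biological replicates per genotype × stage cell
(default 3). Traits belong to one of four levels — phenotype, metabolite,
enzyme (Vmax activity), protein_spot (normalized 2-DE spot volume) — all
expressed on a dry-weight basis so that levels are comparable. Missing
values are first-class throughout: every operation defines its NA
behaviour (pairwise-complete correlations, NA-propagating components,
traits dropped from PCA when their mean matrix has any NA).

## Variation screen

Per trait, a fixed-effects crossed two-way ANOVA with genotype, stage and
interaction terms. Type II sums of squares are used: the nominal design is
balanced, where Type I/II/III coincide, and with missing cells Type II
keeps the decomposition order-invariant. One-way genotype ANOVAs run
within each stage, and within each cross ({P1, P2, F1} only) and stage.
P-values are raw; the screen gates downstream steps at P < 0.05 by design,
and a Benjamini–Hochberg column is emitted for reference only, never used
for gating. Genotype means are simple means over available replicates.
The fold-change summary is max/min of genotype means per stage, NA when
the minimum is not strictly positive. A trait constant within a cell (zero
residual variance with equal means) is reported as "no evidence" (p = 1)
rather than NaN.

## Inheritance decomposition

A and D are computed from replicate means only (no SE weighting). The
five D/A bands use the boundary inclusivity stated above, which makes the
classifier exactly covariant under parent swap: A ↦ −A, D fixed,
dominant ↔ recessive, overdominant ↔ over-recessive. When
|A| ≤ rel_tol·(|A|+|D|) (default rel_tol = 1e-6) the parents are
indistinguishable and the call is `undetermined`: emitting ±∞ ratios would
turn noise into spurious extreme-mode calls. The scan emits a result only
where the within-cross ANOVA is significant (raw P < alpha, default 0.05).

## PCA

Run on genotype means (12 rows per stage, or genotype × stage rows
combined), after autoscaling — consistent with an analysis chain in which
means, not replicates, carry the between-genotype signal. Implementation
is classical SVD of the centred matrix; explained variance sums to 100%
over the full rank; the sign of each component is fixed by making its
largest-magnitude loading positive, so outputs are bit-reproducible.
Zero-variance traits are dropped at autoscaling; traits with any missing
genotype mean are dropped before PCA (the simplest defensible rule;
pairwise-complete covariance can produce non-PSD matrices).

## Correlation networks

Pearson r with two-sided p from the t-transform (n−2 df), computed on
per-stage genotype means (n = number of genotypes). The means basis is the
default because downstream interpretation concerns genetic correlation
among genotypes, not replicate noise; a replicate-level analysis is
available by passing replicate values explicitly. Edges require
|r| > 0.7 AND p < 0.01. The expected-by-chance count is formalized as
alpha × number of tests with a binomial tail probability
P[X ≥ observed], X ~ Binomial(n_tested, alpha); the independence
assumption in that null is a working definition, documented as ours.
A stricter gate (|r| ≥ 0.78, p < 0.001) serves headline tables of spots
tracking fruit weight or dry matter content.

## sPLS

Regression mode with the protein-spot block as predictors. Per component:
power-style updates u ∝ soft(M v), v ∝ soft(Mᵀ u) on the current
cross-covariance M = XᵀY, where soft(·) soft-thresholds at the magnitude
of the (keep+1)-th largest entry so at most `keep` loadings stay non-zero;
convergence when the sign-invariant loading change drops below 1e-9,
error after 500 iterations. Both blocks are deflated on the X-variate
(regression mode). With no sparsity the first component equals the leading
singular pair of XᵀY, which the tests verify against a dense SVD oracle.
Defaults: 3 components, keep_x = min(20, p), keep_y = q (all); only the
0.7 network threshold is a field convention — the component count and
selection sizes are free parameters, logged with every run. The similarity
matrix uses X-variates only (one common convention); entries lie in
[−1, 1] for one component and approximate the X–Y correlations under a
one-factor model. Networks drop isolated nodes and keep edge signs.
The lagged variant pairs X at one stage with Y at another over the same
genotype set, erroring on any mismatch.

## Synthetic panel generator

Per trait: parent mean = baseline + stage effect + genotype effect
(+ a per-(genotype, stage) interaction term for traits flagged with a
genotype × stage interaction). Stage, genotype and interaction effects are
drawn N(0, σ_g²) with σ_g = effect_scale × noise_sd; replicates add iid
Gaussian noise (noise_sd). Defaults: effect_scale 4, noise_sd 1 — a
moderately powered design in which most traits are significantly variable
but calls near classification boundaries remain noisy, matching the
flavour of real panels. The baseline (default 50) keeps values on a
positive concentration-like scale; it cancels everywhere except the
fold-change ratios (which it keeps meaningful).

Hybrid means are planted exactly: per (trait, cross, stage) a mode is
drawn from `mode_distribution` (default 60% additive, 10% each of the
four non-additive modes — predominant additivity with no
dominance/recessivity bias) and a D/A ratio uniform within the mode's
band (open-ended bands capped at |D/A| = 2); the hybrid mean is
midparent + (D/A)·A. Traits without a planted interaction reuse one
(mode, D/A) across stages, because a stage-varying hybrid deviation is
itself a genotype × stage interaction. Interaction frequencies default to
0.93 for phenotypes and metabolites, 0.57 for protein spots, 0.19 for
enzymes — the per-level rates typical of fruit developmental panels.

Correlation blocks: `n_correlation_blocks` groups of `block_size` traits
share a latent genotype factor, g = σ_g(√ρ·z_block + √(1−ρ)·ε), giving
pairwise correlation ≈ ρ (default 0.9) across parent genotype means.
Block members are drawn from interaction-free traits so the planted
correlation is not diluted by stage-specific effects. Hybrid rows dilute
observed block correlations somewhat, because each trait's hybrid
deviation (D/A)·A is idiosyncratic; across all 12 genotypes roughly
70% of planted pairs clear |r| > 0.7 at high signal versus ~95% among
parents only. Ground truth records every planted mode, D/A, interaction
flag, block membership and within-block pair.

What the generator does **not** emulate: heteroscedastic or log-normal
measurement error (a log-normal option exists but is off by default, for
analytic transparency), genotype relatedness structure, linkage between
traits and markers, missing-data patterns, and the long right tails of
secondary-metabolite distributions. Tests passing on synthetic panels
therefore demonstrate correctness of the statistical machinery and
recoverability of planted structure, not robustness to every pathology of
real measurements.

## Determinism and problem sizes

Every stochastic choice in a generated panel flows from one integer seed
through a single `numpy` Generator in fixed order, so regeneration is
bit-identical; the pipeline writes TSVs with a fixed float format and a
SHA-256 manifest, giving checksum-identical reruns. The test suite and the
acceptance script use compact panels (a few dozen traits, the full
12-genotype × 2-stage × 3-replicate design) — recovery rates and error
control are size-stable, and full-scale runs (e.g. 424 protein spots) are
a config change, not a code change.

## Known limitations

* Mode calls near band boundaries are intrinsically noisy: with 3
  replicates and effect_scale 4, the D/A estimate carries an error SD
  around 0.3 at typical parental separations, so the 0.4-wide dominant and
  recessive bands misclassify a substantial share of their draws. Pooled
  planted-mode recovery plateaus in the mid-80% range under those
  defaults; sharper calls need more replicates or stronger effects.
* The chance model for correlation-count excess treats tests as
  independent although pairs sharing a trait are not.
* No correction for genotype relatedness in correlations or sPLS; with 12
  genotypes the analyses describe this panel, not the species.
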