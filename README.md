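# panelomics

Multi-level trait variation, inheritance-mode, and network analysis for
diversity panels of inbred lines and their F1 hybrids.

`panelomics` is aimed at quantitative geneticists and systems biologists
working with panels like the classic tomato fruit designs: a handful of
inbred accessions crossed into F1 hybrids, profiled at several expression
levels — integrative phenotypes (fruit weight, diameter, dry matter
content), metabolite contents, maximal enzyme activities, and 2-DE protein
spot volumes — at two developmental stages with a few biological
replicates. The library covers the full analysis chain for such data, plus
a synthetic panel generator with planted ground truth for validating every
step.

## What it computes

**Variation screen.** Per trait, a fixed-effect two-way ANOVA
(genotype, stage, genotype × stage; Type II sums of squares), one-way
genotype ANOVAs within each stage, and a summary row with significance
stars (`*` 0.01<P<0.05, `**` 0.001<P<0.01, `***` P<0.001), per-stage
min/max genotype means, and the fold-change ratio max/min (NA when
min ≤ 0).

**Inheritance modes.** Within each cross (parents P1, P2 and hybrid F1)
and stage, for traits with a significant within-cross ANOVA (raw P < 0.05):

    A = (mean(P1) − mean(P2)) / 2        additive component
    D = mean(F1) − (mean(P1)+mean(P2))/2  dominance component

with P1 the *S. lycopersicum*-type parent by convention. The D/A ratio is
classified into five bands: over-recessive (D/A < −1.2), recessive
(−1.2 ≤ D/A ≤ −0.8), additive (−0.8 < D/A < 0.8), dominant
(0.8 ≤ D/A ≤ 1.2), overdominant (D/A > 1.2); indistinguishable parents
(A ≈ 0) yield `undetermined` instead of an artifact ±∞ ratio.

**Multivariate overview.** Autoscaling (centre, unit variance) of
genotype means followed by classical SVD-based PCA with a fixed sign
convention, combined across stages or stage by stage.

**Correlation networks.** All-pairs Pearson correlations on genotype
means among screened traits; edges where |r| > 0.7 AND p < 0.01 (at
n = 12 the p-gate corresponds to |r| > 0.708 and is the binding
constraint), with per-level-pair counts compared against the α × tests
expected by chance via a binomial tail.

**sPLS networks.** Sparse partial least squares in regression mode
relating the protein-spot block X to the metabolite/enzyme/phenotype
block Y: per component, power iterations on the cross-covariance with
soft-thresholding that keeps the `keep_x`/`keep_y` largest loadings,
then deflation of both blocks on the X-variate. Networks come from the
similarity matrix M[j,k] = Σ_h cor(X_j, t_h)·cor(Y_k, t_h) thresholded
at 0.7, within one stage or lagged (X at cell expansion, Y at ripening).

## Worked example

```python
import panelomics as po

table, design, truth = po.generate_panel(po.PanelConfig(seed=1))
scan = po.inheritance_scan(table, design, alpha=0.05)
print(scan.head(3).round(3))
print(f"non-additive: {100 * po.nonadditive_fraction(scan):.0f}%")
```

```
trait_id cross_id stage  p_cross      A       D  da_ratio           mode
  phe_01       H1    CE    0.000  3.692  -8.405    -2.277 over_recessive
  phe_02       H1    CE    0.000  4.850  -6.550    -1.351 over_recessive
  phe_03       H1    CE    0.000  4.199   5.312     1.265   overdominant
non-additive: 46%
```

Each row is one trait in one cross at one stage: `A` and `D` are in trait
units, `da_ratio` places the trait in a band, and the pooled non-additive
fraction summarizes how often hybrids deviate from the midparent. The
`examples/` directory has one short script per capability (simulation,
variation screen, inheritance, PCA, correlation networks, sPLS networks);
each prints the numbers it computes and a line on what they mean.

A `panelomics` console command exposes the same steps
(`simulate`, `variation`, `inherit`, `pca`, `corrnet`, `spls`, `run-all`);
`run-all` writes every artifact as TSV plus a `manifest.json` of SHA-256
checksums, bit-identical for identical config and seed.

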