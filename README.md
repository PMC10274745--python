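# xydosage

Tools for quantifying how sex-chromosome constitution modulates genome-wide
expression in human cells. Somatic cells carry one active X (Xa) plus a
variable complement of inactive X (Xi) and Y chromosomes; cohorts spanning
45,X to 49,XXXXY and 49,XYYYY make it possible to treat Xi and Y copy
number as quantitative covariates and ask, gene by gene, how strongly each
autosomal (or Xa-expressed) gene responds. `xydosage` implements that
analysis end to end for anyone studying sex-chromosome dosage, aneuploidy,
X-inactivation escape, or the ZFX/ZFY transcription-factor pair — together
with seeded simulators that generate every input shape with known ground
truth, so each stage is testable without access to controlled raw data.

## The models

**Dosage GLM.** For each gene *g* and sample *s* with `x_s` X chromosomes,
`y_s` Y chromosomes and size factor `sf_s`, counts are modeled as

    K_gs ~ NB(mu_gs, alpha_g),   log2 mu_gs = log2 sf_s + b0_g + bX_g * x_s + bY_g * y_s + batch_gs

with NB variance `mu + alpha * mu^2`. `bX` and `bY` are the log2 fold
changes per added chromosome copy, fitted by per-gene IRLS with a
method-of-moments dispersion, tested with two-sided Wald statistics and
Benjamini–Hochberg correction. The same engine takes arbitrary designs
(Chr 21 trisomy, CRISPRi knockdown contrasts, log2 DYZ1 depth), accepts
fractional copy numbers for mosaic samples, and drives a down-sampling
saturation analysis.

**Escape meta-analysis.** Five published assays of Xi expression report
allelic ratios (AR = reads from the lower-expressed Xi allele over the
higher-expressed Xa allele) in five incompatible dialects. Each dialect
gets a caller implementing that study's inclusion rule and test (one-sample
and paired one-sided t-tests, the per-cell threshold AR > 0.0526 = 1/0.95 − 1,
precomputed adjusted p-values), and the per-study verdicts are combined by
the majority-plus-evidence rule into a final escape / subject / no-call
class, with an Xi-hybrid-line fallback for genes no study covers.

**Comparative statistics.** Hypergeometric set overlaps, Pearson/Spearman
correlation, weighted Deming (errors-in-variables) regression for pairs of
coefficients that both carry estimation error, gene-set enrichment against
an expressed-gene background, and the attribution of copy-number responses
to a regulator knockdown (Deming r² plus per-gene effect ratios).

**Genome structure.** GC-corrected read-depth ratios over the DYZ1
satellite quantify Yq heterochromatin length; batch-residualized PCA with
per-group 95% confidence ellipses places structurally variant samples among
karyotype groups; interval queries assign ChIP peaks to promoter windows.

## Worked example

`examples/01_cohort_dosage_fit.py` simulates a 120-sample, 1,000-gene
cohort across nine karyotypes with 10% responsive genes and refits it:

```
cohort: 1000 genes x 120 samples, 9 karyotypes
X-responsive calls (padj<0.05): 61 of 70 truly responsive genes
RMSE of estimated vs true log2FC per X copy: 0.090
false discoveries among calls: 3 (empirical FDR 0.049)
```

The fit recovers the per-copy effects to within 0.09 log2 units and the
BH-corrected calls keep the false discovery rate at the nominal 5%. The
other examples cover the escape meta-analysis (`02`), Deming comparison and
knockdown attribution (`03`), and DYZ1 depth recovery plus karyotype PCA
(`04`); each prints the quantities it computes and a line on how to read
them.

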