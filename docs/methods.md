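# Methods

## Count model and inference

Counts are modeled per gene as negative binomial with log link,
`variance = mu + alpha * mu^2` (the dominant convention in count-based
differential expression). The linear predictor contains an intercept, the
copy-number covariates of interest (X, Y, and optionally Chr 21 copies, or
log2 DYZ1 depth), and categorical nuisance covariates (library batch,
population, lab, CRISPRi target, cell line) dummy-coded against a reference
level. Copy numbers may be fractional: mosaic samples (e.g. a culture that
is 47% 46,X,i(Xq) / 53% 45,X) are represented by their expected copy
number, since bulk expression averages across subclones.

Fitting is iteratively reweighted least squares, batched across genes
(shared design, per-gene weights), with working weights
`mu / (1 + alpha*mu)`, a relative NB-deviance convergence tolerance of
1e-8 and at most 100 iterations; non-converged genes are flagged and
excluded from multiplicity correction. Standard errors come from the
expected information at the optimum, coefficients are reported in log2
units, and Wald statistics are referred to the standard normal, two-sided
— responses in both directions are real and reported. A unit-test oracle
checks the IRLS solution against statsmodels' NB GLM and against direct
profile maximization of the exact NB log-likelihood.

Dispersion is estimated per gene by method of moments around
Poisson-fitted means, `alpha = [RSS * n/(n-p) - sum(mu)] / sum(mu^2)`,
floored at 1e-8, with optional (off by default) geometric shrinkage toward
an `a0 + a1/mean` trend. The full empirical-Bayes machinery of dedicated
DE packages is deliberately not reproduced: the inference target here is
the per-copy coefficient, and at the cohort sizes involved the
method-of-moments estimate is adequate (the parameter-recovery and FDR
acceptance checks quantify exactly how adequate). No fold-change shrinkage
is applied — raw model coefficients are the reported effect sizes — and
neither independent filtering nor outlier-based count exclusion is
performed; expression filtering happens once, up front (genes with median
TPM >= 1 in euploid 46,XX or 46,XY samples of the cell type, boundary
inclusive).

Size factors are median-of-ratios: the per-gene reference is the geometric
mean across samples, genes containing any zero count are excluded from the
reference (a pseudocount fallback is available behind a flag), and factors
are rescaled to geometric mean 1. Computing the reference on a gene subset
(e.g. autosomes only) supports the robustness check that removing
sex-linked genes from normalization leaves coefficients essentially
unchanged; a test asserts < 0.05 log2 units of movement when the planted
responsive genes are a small library fraction.

BH correction is applied separately per covariate of interest, per cell
type, over the filtered expressed genes — responsive-gene counts are
reported per cell type and chromosome, so that is the family that matters.

The saturation analysis redraws `n` samples without replacement (100
repetitions per size by default), reruns normalization, dispersion and
fitting on each subset, and records the number of padj < 0.05 genes.
Subsets that leave the design rank-deficient are redrawn with a bounded
retry count.

## Escape meta-analysis

Allelic ratio (AR) is the ratio of reads from the lower- to the
higher-expressed allele, so AR = 0 is monoallelic and AR = 1 balanced.
Two conversions recur: an active-X read fraction `f` maps to
`AR = 1/f - 1`, and a sample with skewing coefficient `s` (fraction of
cells inactivating the same parental X) has baseline
`AR = (1-s)/s` under complete silencing — the expected ratio when the
minority-cell population alone contributes the "Xi" reads.

The five dialect callers implement each study's published inclusion rule
and test verbatim: per-gene summary statistics with n >= 5 and a one-sided
one-sample t-test (BH, padj < 0.05); a two-arm study with precomputed
adjusted p-values, included at >= 2 single-cell individuals or 1 plus bulk,
escape if either arm is significant (OR rule; escape wins on
disagreement); single-cell ARs with >= 2 informative samples and a strict
per-sample threshold of AR > 0.0526; skew-adjusted bulk ARs with >= 10
informative samples and a paired one-sided t-test against the per-sample
baseline (BH, padj < 0.01); and per-sample bulk ARs summarized and tested
against zero (BH, padj < 0.05, minimum two samples so the t-test is
defined — no minimum is published for this dialect). Degenerate cases are
total: zero spread with positive mean is escape with p = 0; identically
zero paired differences give p = 0.5.

The combiner is a deterministic three-way rule over the per-study
verdicts, with studies lacking data excluded from both numerator and
denominator: escape if > 50% of data-bearing studies say escape, or if
<= 50% (but > 0) do and either more than one study shows escape or the
unweighted cross-study mean AR is >= 0.1; subject if all data-bearing
studies say subject, or > 50% do and the mean AR is < 0.1. The tie cell
(exactly half escaping, one escaping study, mean AR < 0.1) is left
no-call, since neither ruleset fires. Genes with no study data fall back
to the fraction of human–rodent Xi-hybrid lines expressing the gene:
>= 22% is escape; below that the default is subject (the published rule is
stated only in the escape direction; the alternative of leaving such genes
uncalled is selectable). All thresholds are fields of `EscapeThresholds`
defaulting to the published values. A test enumerates all 3^5 study
patterns crossed with AR and hybrid states against an independent literal
restatement of the rules, and a property test checks monotonicity under
single-study flips.

## Comparative statistics

Unweighted Deming regression uses the closed-form errors-in-variables
slope with error-variance ratio 1 (orthogonal regression). The weighted
fit takes per-point standard errors on both axes and minimizes total
weighted orthogonal squared distance,
`sum_i (y_i - a - b x_i)^2 / (sy_i^2 + b^2 sx_i^2)`, by York-style
iterative reweighting (slope tolerance 1e-8, max 200 iterations) — the
same contract as the reference R implementation, written independently. A
grid-search minimizer of the loss serves as the acceptance oracle.

"Fraction of effects explained" by a knockdown is not operationally
defined in the literature this package serves, so both candidates are
computed: the r² of the weighted Deming pair (negated knockdown log2FC
versus per-copy log2FC), reported as primary since figure captions cite
coefficients of determination, and the per-gene ratio
`100 * clip(-b_kd / b_chr, 0, 1)` with its quartiles as the secondary,
gene-level reading.

Set overlaps use the upper-tail hypergeometric distribution; gene-set
enrichment restricts memberships to the expressed-gene background of the
relevant cell type (never the whole genome) before testing, with BH across
sets.

## Genome structure

GC correction estimates a GC → relative-depth curve from single-copy bins
only — binned medians over 20 equal-width GC bins, normalized to the
overall single-copy median — and divides every bin's depth by the curve
interpolated at its GC. Fitting on single-copy bins prevents copy-number
signal from leaking into the correction; identical-GC profiles reduce to
the identity. The DYZ1 ratio is then corrected mean DYZ1 depth over
corrected mean single-copy depth, invariant to global depth rescaling.

PCA uses log2(normalized count + 1) as a variance-stabilizing surrogate:
the clustering conclusions rest on large between-karyotype separations,
not on the exact transform, and the simpler transform keeps the stage
dependency-free. Batch effects are removed by per-gene least-squares
residualization on batch indicators (the same contract as limma's
removeBatchEffect); genes are centered and unit-scaled and samples
projected by SVD. Group ellipses are the chi-square(2) contours of the
group sample covariance at the requested level (5.991 at 95%), drawn only
for groups with at least three samples; singular covariances are flagged
degenerate rather than drawn.

Coordinates are 0-based half-open throughout (BED convention); the TSS of
a − strand gene is its interval end. A gene is "bound" if any peak
overlaps `[TSS - w, TSS + w)` — closed-open, clipped at zero, so a peak
abutting the window end does not bind. Binding proportion divides the
number of expressing cell lines with promoter binding by the number of
expressing lines, excluding non-expressing lines from both sides.

## Synthetic data

The cohort generator draws counts from the NB law above with per-gene
baselines (log2 means ~ Normal(5, 2)), log-normal dispersions centered at
0.05, log-normal library sizes (sigma 0.3), and Normal(0, 0.1) per-batch
log2 offsets across three batches. The default karyotype table spans nine
constitutions from 45,X to 49,XYYYY over 120 samples, weighted toward the
euploid groups as cohorts of this kind are. Truth classes partition genes
(null / X / Y / shared / Chr 21-responsive; defaults 5% / 3% / 2% X, Y and
shared); shared genes receive same-sign X and Y effects, reflecting a
common mechanism. Effect magnitudes default to |log2FC| uniform on
[0.1, 0.6] per copy — responses mostly under 1.5-fold, with magnitudes
otherwise free parameters of the config.

The allelic generator draws true Xi/Xa ratios from Uniform(0.15, 0.6) for
escape genes and Exponential(0.002) for subject genes — silenced means
silenced, up to trace background — and observes them through binomial
allele-count sampling (40–200 reads), so subject genes mostly report
exactly zero Xi reads, as real data do. Study dialects add their own
structure: per-study sample counts and missingness, skewing coefficients
drawn Uniform(0.7, 1.0), and precomputed adjusted p-values generated with
95% detection power for covered escape genes.

The depth generator emulates per-bin depths as
`base * copy * (1 + A * sin(2*pi*(gc - 0.5))) * lognormal noise`, with
DYZ1 GC content running higher (0.50–0.72) than the single-copy region
(0.30–0.70) so an uncorrected ratio inherits the GC bias. Default copy
numbers are uniform over 20–900, matching the observed range of DYZ1
ratios.

What the simulators do not emulate: correlated gene-gene expression,
gene-specific GC or length biases in counts, mappability structure,
phasing or genotyping error in allelic counts, and cell-type-specific
expression differences beyond what the configs encode. Passing the
recovery tests therefore demonstrates correctness of the estimators under
the stated generative laws, not robustness to every artifact of real
RNA-seq.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale problems chosen to
make the Monte-Carlo checks sharp: 1,000 genes x 120 samples for
coefficient recovery and null calibration, 500 genes across the five
allelic dialects, 60 depth profiles, and a saturation sweep of sizes
20–120 with 25 repetitions on a 400-gene cohort planted with small
(|log2FC| in [0.05, 0.35]) effects — the unsaturated regime in which the
claim "more samples keep discovering more genes" lives. Ties, degenerate
inputs and guard rails: IRLS linear predictors are clipped at ±30, normal
equations carry a 1e-10 ridge so all-zero genes stay solvable, dispersion
is floored at 1e-8, BH propagates NaN inputs without counting them, and
zero-variance correlation inputs raise rather than return NaN.

## Known limitations

The dispersion estimator is unshrunk by default and noisy at small n; the
per-gene Wald test is anti-conservative for very low counts (no
independent filtering is applied); the weighted Deming fit assumes
uncorrelated errors between axes; and the escape combiner inherits the
published rules' asymmetry, including the undefined tie cell and the
one-directional hybrid rule, both resolved as documented above.
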