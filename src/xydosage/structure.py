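"""Depth-based heterochromatin quantification, PCA of responsive genes, and
peak-to-promoter assignment.

The Yq heterochromatic block is a tandem array of the DYZ1 satellite; its
length varies widely between Y chromosomes and is indexed by the ratio of
GC-corrected read depth over DYZ1 to that over a single-copy reference
region of Chr Y. Structural-variant samples are placed among karyotype
groups by PCA of responsive-gene expression with per-group 95% confidence
ellipses. Transcription-factor binding at promoters is scored by interval
overlap between ChIP peaks and a window around each gene's TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .dosage import DosageFitResult, build_design, fit_dosage_model

DYZ1 = "DYZ1"
SINGLE_COPY = "single_copy"

__all__ = [
    "gc_correct_depth",
    "dyz1_ratio",
    "fit_depth_expression_model",
    "transform_and_pca",
    "group_ellipse",
    "assign_peaks_to_genes",
    "binding_proportion",
    "PcaProjection",
]


# ---------------------------------------------------------------------------
# GC correction and depth ratios
# ---------------------------------------------------------------------------

def gc_correct_depth(profile: pd.DataFrame, n_gc_bins: int = 20) -> pd.DataFrame:
    """Correct binned depths of one sample for GC bias.

    ``profile`` is a per-bin table with columns ``region`` (``DYZ1`` or
    ``single_copy``), ``gc_fraction`` and ``depth``. The GC -> relative
    depth curve is estimated from the single-copy bins only (binned medians
    over ``n_gc_bins`` equal-width GC bins, normalized to overall median 1)
    so that copy-number signal in DYZ1 cannot leak into the correction;
    every bin's depth is then divided by the curve value interpolated at
    its GC. Returns a copy with a ``depth_corrected`` column.
    """
    out = profile.copy()
    sc = out[out["region"] == SINGLE_COPY]
    if len(sc) < 2:
        raise ValueError("need single-copy bins to estimate the GC bias curve")
    gc = sc["gc_fraction"].to_numpy(dtype=float)
    depth = sc["depth"].to_numpy(dtype=float)
    gmin, gmax = gc.min(), gc.max()
    if gmax == gmin:
        out["depth_corrected"] = out["depth"].astype(float)
        return out
    edges = np.linspace(gmin, gmax, n_gc_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(gc, edges) - 1, 0, n_gc_bins - 1)
    med = np.array([np.median(depth[idx == b]) if (idx == b).any() else np.nan for b in range(n_gc_bins)])
    ok = np.isfinite(med)
    overall = np.median(depth)
    factor = med[ok] / overall
    bias = np.interp(out["gc_fraction"].to_numpy(dtype=float), centers[ok], factor)
    bias = np.clip(bias, 1e-6, None)
    out["depth_corrected"] = out["depth"].to_numpy(dtype=float) / bias
    return out


def dyz1_ratio(profile: pd.DataFrame) -> float:
    """Corrected mean DYZ1 depth over corrected mean single-copy depth.

    Runs :func:`gc_correct_depth` first if the profile has no
    ``depth_corrected`` column. Invariant to global rescaling of the
    sample's depth.
    """
    if "depth_corrected" not in profile.columns:
        profile = gc_correct_depth(profile)
    means = profile.groupby("region")["depth_corrected"].mean()
    if DYZ1 not in means.index or SINGLE_COPY not in means.index:
        raise ValueError("profile must contain both DYZ1 and single_copy regions")
    if means[SINGLE_COPY] <= 0:
        raise ValueError("zero single-copy coverage: ratio undefined")
    return float(means[DYZ1] / means[SINGLE_COPY])


def fit_depth_expression_model(
    counts: pd.DataFrame,
    depth_ratios: pd.Series,
    covariates: pd.DataFrame | None = None,
    **fit_kwargs,
) -> DosageFitResult:
    """Model expression as a function of log2 DYZ1 depth ratio.

    Builds a design with the continuous covariate ``log2_depth`` plus any
    categorical confounders supplied in ``covariates`` (e.g. population and
    sequencing lab) and delegates to the NB dosage engine. The reported
    coefficient is the log2 fold change per doubling of DYZ1 content.
    """
    ratios = depth_ratios.reindex(counts.columns)
    if (ratios <= 0).any() or ratios.isna().any():
        raise ValueError("depth ratios must be positive for all samples")
    sheet = pd.DataFrame({"log2_depth": np.log2(ratios)}, index=counts.columns)
    covs = ["log2_depth"]
    if covariates is not None:
        for c in covariates.columns:
            sheet[c] = covariates.reindex(counts.columns)[c]
            covs.append(c)
    design = build_design(sheet, covs)
    return fit_dosage_model(
        counts, sheet, design, covariates_of_interest=["log2_depth"], **fit_kwargs
    )


# ---------------------------------------------------------------------------
# PCA with group ellipses
# ---------------------------------------------------------------------------

@dataclass
class PcaProjection:
    scores: pd.DataFrame            # samples x components
    variance_fraction: np.ndarray   # per component, non-increasing
    ellipses: dict                  # group -> ellipse parameters


def transform_and_pca(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    gene_set,
    batch: pd.Series | None = None,
    n_components: int = 2,
    group_labels: pd.Series | None = None,
    level: float = 0.95,
) -> PcaProjection:
    """Variance-stabilized, batch-corrected PCA of a gene set.

    Normalized counts are transformed as log2(count/sf + 1); batch effects
    are removed by per-gene least-squares residualization on batch
    indicator columns (retaining the intercept); genes are centered and
    unit-scaled, and samples are projected by SVD. Confidence ellipses are
    drawn per ``group_labels`` group with at least three samples.
    """
    genes = [g for g in gene_set if g in counts.index]
    if not genes:
        raise ValueError("gene set empty after intersecting with the count matrix")
    if counts.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    mat = np.log2(counts.loc[genes].to_numpy(dtype=float) / sf[None, :] + 1.0)
    if batch is not None:
        b = batch.reindex(counts.columns).astype(str)
        dummies = pd.get_dummies(b, drop_first=True).to_numpy(dtype=float)
        if dummies.shape[1]:
            B = np.column_stack([np.ones(mat.shape[1]), dummies])
            coef, *_ = np.linalg.lstsq(B, mat.T, rcond=None)
            mat = mat - (dummies @ coef[1:]).T
    mat = mat - mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1)
    mat = mat / np.where(sd > 0, sd, 1.0)[:, None]
    X = mat.T  # samples x genes
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(S))
    scores = pd.DataFrame(
        U[:, :k] * S[:k],
        index=counts.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    total_var = (S**2).sum()
    var_frac = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    ellipses = {}
    if group_labels is not None:
        ellipses = {
            g: e
            for g, e in group_ellipse(scores.iloc[:, :2], group_labels.reindex(counts.columns), level=level).items()
        }
    return PcaProjection(scores=scores, variance_fraction=var_frac, ellipses=ellipses)


def group_ellipse(scores: pd.DataFrame, groups: pd.Series, level: float = 0.95) -> dict:
    """Per-group confidence ellipses on the first two components.

    Each group with at least three samples gets an ellipse centered at the
    group mean with shape matrix = sample covariance scaled by the
    chi-square(2) quantile at ``level`` (5.991 at 0.95). Groups whose
    covariance is singular (e.g. collinear points) are flagged degenerate.
    """
    if not 0 <= level < 1:
        raise ValueError("level must lie in [0, 1)")
    scale = float(stats.chi2.ppf(level, df=2)) if level > 0 else 0.0
    out = {}
    for g, idx in groups.groupby(groups).groups.items():
        pts = scores.loc[idx].to_numpy(dtype=float)[:, :2]
        if pts.shape[0] < 3:
            continue
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        eigvals = np.linalg.eigvalsh(cov)
        degenerate = bool(np.min(eigvals) <= 1e-12 * max(np.max(eigvals), 1e-300))
        semi_axes = np.sqrt(np.clip(eigvals, 0.0, None)[::-1] * scale)
        out[g] = {
            "center": center,
            "cov": cov,
            "scale": scale,
            "semi_axes": semi_axes,
            "n": pts.shape[0],
            "degenerate": degenerate,
        }
    return out


# ---------------------------------------------------------------------------
# peak-to-gene assignment
# ---------------------------------------------------------------------------

def tss_positions(annotation: pd.DataFrame) -> pd.Series:
    """TSS per gene under the BED convention: interval start on the + strand,
    interval end on the - strand (0-based half-open)."""
    strand = annotation["strand"]
    return pd.Series(
        np.where(strand == "+", annotation["start"], annotation["end"]),
        index=annotation.index,
        name="tss",
    )


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int = 1000,
    warn_unknown_chroms: bool = True,
) -> pd.Series:
    """Flag genes with a peak overlapping [TSS - window, TSS + window).

    ``peaks`` is a BED-like frame (``chrom``, ``start``, ``end``);
    ``annotation`` carries ``chromosome``, ``start``, ``end``, ``strand``
    per gene. Windows are clipped at zero and treated closed-open: a peak
    abutting the window end does not bind. Peaks on chromosomes absent
    from the annotation are skipped.
    """
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError("invalid peak intervals (start >= end)")
    known = set(annotation["chromosome"].unique())
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom"):
        if chrom not in known:
            continue
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].astype(int), sub["end"].astype(int))
        )
    tss = tss_positions(annotation)
    bound = {}
    for gene, row in annotation.iterrows():
        t = int(tss[gene])
        lo, hi = max(t - window, 0), t + window
        tree = trees.get(row["chromosome"])
        bound[gene] = bool(tree is not None and lo < hi and tree.overlap(lo, hi))
    return pd.Series(bound, name="bound")


def binding_proportion(bound: pd.DataFrame, expressed: pd.DataFrame) -> pd.Series:
    """Fraction of expressing cell lines in which a gene's promoter is bound.

    ``bound`` and ``expressed`` are genes x cell-line boolean frames; lines
    in which a gene is not expressed are excluded from both numerator and
    denominator. Genes expressed in no line get NaN.
    """
    lines = [c for c in bound.columns if c in expressed.columns]
    b = bound[lines].to_numpy(dtype=bool)
    e = expressed[lines].to_numpy(dtype=bool)
    denom = e.sum(axis=1)
    numer = (b & e).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(denom > 0, numer / np.maximum(denom, 1), np.nan)
    return pd.Series(frac, index=bound.index, name="binding_proportion")
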