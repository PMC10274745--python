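"""Per-gene negative-binomial dosage models of expression counts.

This module fits, for every gene, a log-linear negative-binomial GLM of raw
read counts against chromosome copy numbers (or any design built from the
sample sheet):

    count[g, s] ~ NB(mean = sf_s * exp(X_s beta_g), variance = mu + alpha_g mu^2)

The coefficient of a copy-number covariate, reported in log2 units, is the
fold change in expression per additional chromosome copy. The surrounding
machinery — TPM computation, the expressed-gene filter, median-of-ratios
size factors, method-of-moments dispersion, Wald tests with
Benjamini-Hochberg correction, and the down-sampling saturation analysis —
mirrors the standard count-based differential-expression workflow, but the
model engine itself is a batched IRLS implemented here so that arbitrary
(including fractional, mosaic) copy-number designs are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)

__all__ = [
    "build_design",
    "compute_tpm",
    "filter_expressed",
    "compute_size_factors",
    "estimate_dispersion",
    "adjust_bh",
    "fit_dosage_model",
    "saturation_analysis",
    "DosageFitResult",
]


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(
    samples: pd.DataFrame,
    covariates: Sequence[str],
    reference: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Build a full-rank design matrix from sample-sheet columns.

    Numeric columns enter as-is (fractional copy numbers are allowed, which
    is how mosaic samples are represented); non-numeric columns are dummy
    coded against a reference level (by default the first level in sorted
    order, overridable via ``reference``). An intercept is always included.

    Raises ``ValueError`` naming the aliased columns if the result is
    rank deficient.
    """
    reference = dict(reference or {})
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(samples))}
    for cov in covariates:
        if cov == "intercept":
            continue
        if cov not in samples.columns:
            raise ValueError(f"covariate {cov!r} not in sample sheet")
        col = samples[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols[cov] = col.to_numpy(dtype=float)
        else:
            levels = sorted(col.astype(str).unique())
            ref = str(reference.get(cov, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {cov!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{cov}[{lev}]"] = (col.astype(str) == lev).to_numpy(float)
    X = pd.DataFrame(cols, index=samples.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _aliased_columns(X.to_numpy())
        names = [X.columns[i] for i in aliased]
        raise ValueError(f"design matrix rank deficient; aliased columns: {names}")
    return X


def _aliased_columns(X: np.ndarray) -> list[int]:
    """Indices of columns that add no rank (via pivoted QR diagnostics)."""
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [i for i, d in enumerate(diag) if d <= tol]


# ---------------------------------------------------------------------------
# TPM and filtering
# ---------------------------------------------------------------------------

def compute_tpm(counts: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Transcripts-per-million from counts and effective gene lengths.

    ``annotation`` must carry an ``effective_length`` (bases) per gene, indexed
    by gene id. Columns of the result sum to 1e6.
    """
    lengths = annotation["effective_length"].reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"genes missing effective_length, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("effective_length must be positive")
    rate = counts.div(lengths, axis=0)
    total = rate.sum(axis=0)
    zero = total[total <= 0]
    if len(zero):
        raise ValueError(f"zero total length-normalized rate in sample(s) {list(zero.index)}")
    return rate.div(total, axis=1) * 1e6


def filter_expressed(
    tpm: pd.DataFrame,
    samples: pd.DataFrame,
    threshold: float = 1.0,
    cell_types: Sequence[str] | None = None,
) -> dict[str, pd.Index]:
    """Expressed-gene sets per cell type.

    A gene is retained in a cell type if its median TPM across the euploid
    46,XX samples (x=2, y=0) or across the euploid 46,XY samples (x=1, y=1)
    of that cell type is at least ``threshold`` (inclusive).
    """
    out: dict[str, pd.Index] = {}
    types = cell_types if cell_types is not None else sorted(samples["cell_type"].unique())
    for ct in types:
        sub = samples[samples["cell_type"] == ct]
        xx = sub.index[(sub["x_copies"] == 2) & (sub["y_copies"] == 0)]
        xy = sub.index[(sub["x_copies"] == 1) & (sub["y_copies"] == 1)]
        if len(xx) == 0 and len(xy) == 0:
            raise ValueError(f"no euploid (46,XX or 46,XY) samples in cell type {ct!r}")
        keep = np.zeros(tpm.shape[0], dtype=bool)
        if len(xx):
            keep |= (tpm[xx].median(axis=1) >= threshold).to_numpy()
        if len(xy):
            keep |= (tpm[xy].median(axis=1) >= threshold).to_numpy()
        out[ct] = tpm.index[keep]
    return out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def compute_size_factors(
    counts: pd.DataFrame,
    gene_subset: Sequence[str] | None = None,
    allow_pseudo_reference: bool = False,
) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The per-gene reference is the geometric mean of counts across samples;
    genes containing any zero count are excluded from the reference (set
    ``allow_pseudo_reference`` to fall back to geometric means over a +0.5
    pseudocount when no gene survives). ``gene_subset`` restricts the
    reference genes, e.g. to autosomal genes only.
    """
    mat = counts.loc[list(gene_subset)] if gene_subset is not None else counts
    if mat.shape[0] == 0:
        raise ValueError("empty gene subset for size-factor computation")
    arr = mat.to_numpy(dtype=float)
    usable = (arr > 0).all(axis=1)
    if not usable.any():
        if not allow_pseudo_reference:
            raise ValueError(
                "no genes without zero counts; pass allow_pseudo_reference=True "
                "to use a pseudocount reference"
            )
        arr = arr + 0.5
        usable = np.ones(arr.shape[0], dtype=bool)
    sub = arr[usable]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    ratios = sub / ref[:, None]
    sf = np.median(ratios, axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# batched IRLS engine
# ---------------------------------------------------------------------------

def _nb_deviance(Y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Negative-binomial deviance per gene (columns)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(Y > 0, Y * np.log(np.where(Y > 0, Y, 1.0) / mu), 0.0)
    inv_a = 1.0 / alpha[None, :]
    term2 = (Y + inv_a) * (np.log1p(alpha[None, :] * Y) - np.log1p(alpha[None, :] * mu))
    return 2.0 * np.sum(term1 - term2, axis=0)


def _irls_nb(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB GLMs with log link for all genes at once.

    Parameters are natural-log scale. Returns ``(beta (p,G), se (p,G),
    converged (G,))``. All genes share the design ``X`` (n, p); ``offset``
    is the per-sample log size factor.

    Iteratively reweighted least squares with working weights
    ``w = mu / (1 + alpha*mu)``; convergence on the relative change of the
    NB deviance (tolerance ``tol``, at most ``max_iter`` iterations).
    """
    n, G = Y.shape
    p = X.shape[1]
    off = offset[:, None]
    # initialize from a log-linear regression on lightly regularized counts
    z0 = np.log(Y + 0.5) - off
    beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    dev_old = np.full(G, np.inf)
    converged = np.zeros(G, dtype=bool)
    active = np.arange(G)
    for _ in range(max_iter):
        if active.size == 0:
            break
        eta = np.clip(X @ beta[:, active] + off, -30.0, 30.0)
        mu = np.exp(eta)
        Ya = Y[:, active]
        aa = alpha[active]
        W = mu / (1.0 + aa[None, :] * mu)
        z = (eta - off) + (Ya - mu) / mu
        A = np.einsum("np,ng,nq->gpq", X, W, X, optimize=True)
        b = np.einsum("np,ng->gp", X, W * z, optimize=True)
        # ridge whisper keeps degenerate genes (e.g. all-zero) solvable
        A = A + 1e-10 * np.eye(p)[None, :, :]
        beta_new = np.linalg.solve(A, b[:, :, None])[:, :, 0].T
        beta[:, active] = beta_new
        eta = np.clip(X @ beta[:, active] + off, -30.0, 30.0)
        dev = _nb_deviance(Ya, np.exp(eta), aa)
        rel = np.abs(dev - dev_old[active]) / (np.abs(dev) + 0.1)
        done = rel < tol
        converged[active[done]] = True
        dev_old[active] = dev
        active = active[~done]
    # standard errors from the expected information at the optimum
    eta = np.clip(X @ beta + off, -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[None, :] * mu)
    A = np.einsum("np,ng,nq->gpq", X, W, X, optimize=True)
    A = A + 1e-10 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0)).T
    return beta, se, converged


def estimate_dispersion(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    design: pd.DataFrame,
    floor: float = 1e-8,
    shrink_to_trend: bool = False,
    trend_weight: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments around fitted means.

    A Poisson GLM (the alpha → 0 limit of the NB IRLS) supplies fitted means
    ``mu`` under the design; the dispersion estimate is then

        alpha_g = [ sum((y - mu)^2) * n/(n - p) - sum(mu) ] / sum(mu^2)

    floored at ``floor``. With ``shrink_to_trend`` the log-dispersions are
    pulled toward a mean-dispersion trend ``a0 + a1/mean`` fitted across
    genes (geometric interpolation with weight ``trend_weight``); off by
    default — coefficient inference, not dispersion itself, is the target.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{n} samples cannot identify {p} design columns")
    Y = counts.to_numpy(dtype=float)
    offset = np.log(size_factors.reindex(counts.columns).to_numpy(dtype=float))
    beta, _, _ = _irls_nb(np.ascontiguousarray(Y.T), X, offset, np.full(Y.shape[0], 1e-12))
    mu = np.exp(np.clip(X @ beta + offset[:, None], -30.0, 30.0))
    resid2 = (Y.T - mu) ** 2
    num = resid2.sum(axis=0) * (n / (n - p)) - mu.sum(axis=0)
    den = (mu**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, floor)
    alpha = np.maximum(alpha, floor)
    if shrink_to_trend:
        base_mean = mu.mean(axis=0)
        ok = (alpha > floor) & (base_mean > 0)
        if ok.sum() >= 10:
            A = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
            coef, *_ = np.linalg.lstsq(A, alpha[ok], rcond=None)
            trend = np.maximum(coef[0] + coef[1] / np.maximum(base_mean, 1e-8), floor)
            alpha = np.exp(
                (1 - trend_weight) * np.log(alpha) + trend_weight * np.log(trend)
            )
    return pd.Series(alpha, index=counts.index, name="alpha")


# ---------------------------------------------------------------------------
# testing
# ---------------------------------------------------------------------------

def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the number of tests and propagated as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        if ((p[mask] < 0) | (p[mask] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


@dataclass
class DosageFitResult:
    """Per-gene NB GLM results.

    ``tables`` maps each covariate of interest to a DataFrame with columns
    ``log2FC`` (log2 units per unit covariate), ``SE``, ``stat`` (Wald z),
    ``p`` and ``padj`` (BH across converged genes for that covariate).
    """

    base_mean: pd.Series
    tables: dict[str, pd.DataFrame]
    alpha: pd.Series
    converged: pd.Series
    design_columns: list[str] = field(default_factory=list)

    def significant(self, covariate: str, threshold: float = 0.05) -> pd.Index:
        t = self.tables[covariate]
        return t.index[t["padj"] < threshold]


def fit_dosage_model(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    design: pd.DataFrame | Sequence[str],
    size_factors: pd.Series | None = None,
    alpha: pd.Series | None = None,
    covariates_of_interest: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> DosageFitResult:
    """Fit the per-gene NB dosage model and Wald-test each covariate.

    ``design`` is either a design matrix aligned to ``counts`` columns or a
    list of sample-sheet column names passed to :func:`build_design`.
    Coefficients are reported in log2 units; two-sided Wald p-values against
    the standard normal are BH-adjusted per covariate over converged genes.
    Non-converged genes are flagged and excluded from multiplicity
    correction.
    """
    if not isinstance(design, pd.DataFrame):
        design = build_design(samples.loc[counts.columns], list(design))
    X = design.loc[counts.columns].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = [design.columns[i] for i in _aliased_columns(X)]
        raise ValueError(f"design matrix rank deficient; aliased columns: {aliased}")
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    if alpha is None:
        alpha = estimate_dispersion(counts, size_factors, design)
    a = alpha.reindex(counts.index).to_numpy(dtype=float)
    Y = counts.to_numpy(dtype=float).T  # samples x genes
    beta, se, converged = _irls_nb(Y, X, np.log(sf), a, max_iter=max_iter, tol=tol)
    norm = counts.to_numpy(dtype=float) / sf[None, :]
    base_mean = pd.Series(norm.mean(axis=1), index=counts.index, name="baseMean")

    cov_names = list(design.columns)
    if covariates_of_interest is None:
        covariates_of_interest = [c for c in cov_names if c != "intercept"]
    tables: dict[str, pd.DataFrame] = {}
    for covname in covariates_of_interest:
        j = cov_names.index(covname)
        b = beta[j] / LN2
        s = se[j] / LN2
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(s > 0, beta[j] / se[j], 0.0)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        pvals = np.where(converged, pvals, np.nan)
        padj = adjust_bh(pvals)
        tables[covname] = pd.DataFrame(
            {"log2FC": b, "SE": s, "stat": z, "p": pvals, "padj": padj},
            index=counts.index,
        )
    return DosageFitResult(
        base_mean=base_mean,
        tables=tables,
        alpha=pd.Series(a, index=counts.index, name="alpha"),
        converged=pd.Series(converged, index=counts.index, name="converged"),
        design_columns=cov_names,
    )


# ---------------------------------------------------------------------------
# saturation analysis
# ---------------------------------------------------------------------------

def saturation_analysis(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    design_covariates: Sequence[str],
    sizes: Sequence[int],
    reps: int = 100,
    seed: int = 0,
    covariates_of_interest: Sequence[str] | None = None,
    padj_threshold: float = 0.05,
    max_redraws: int = 50,
) -> pd.DataFrame:
    """Down-sampling saturation of discovered responsive genes.

    For each sample size ``n`` and each of ``reps`` repetitions, draw ``n``
    samples without replacement, re-run normalization, dispersion
    estimation and the NB fit on the subset, and record the number of genes
    with ``padj`` below threshold per covariate of interest. Subsets that
    leave the design rank deficient are redrawn (up to ``max_redraws``
    times).
    """
    rng = np.random.default_rng(seed)
    total = counts.shape[1]
    full_design = build_design(samples.loc[counts.columns], list(design_covariates))
    min_n = full_design.shape[1] + 1
    rows = []
    for n in sizes:
        if n > total:
            raise ValueError(f"subsample size {n} exceeds cohort size {total}")
        if n < min_n:
            raise ValueError(f"subsample size {n} below minimum identifiable size {min_n}")
        for rep in range(reps):
            for _ in range(max_redraws):
                chosen = list(rng.choice(counts.columns, size=n, replace=False))
                sub_samples = samples.loc[chosen]
                try:
                    design = build_design(sub_samples, list(design_covariates))
                except ValueError:
                    continue
                break
            else:
                raise ValueError(f"could not draw a full-rank subsample of size {n}")
            sub_counts = counts[chosen]
            sf = compute_size_factors(sub_counts, allow_pseudo_reference=True)
            fit = fit_dosage_model(
                sub_counts,
                sub_samples,
                design,
                size_factors=sf,
                covariates_of_interest=covariates_of_interest,
            )
            for covname, table in fit.tables.items():
                rows.append(
                    {
                        "n": n,
                        "rep": rep,
                        "covariate": covname,
                        "n_significant": int((table["padj"] < padj_threshold).sum()),
                    }
                )
    return pd.DataFrame(rows)
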