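"""Statistics comparing per-gene response vectors.

Covers the downstream comparisons between fitted dosage responses:
hypergeometric set overlaps, Pearson/Spearman correlation, (weighted)
Deming errors-in-variables regression for pairs of coefficients that both
carry estimation error, gene-set enrichment against an expressed-gene
background, and the attribution of copy-number effects to a
knockdown-derived response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dosage import adjust_bh

__all__ = [
    "OverlapTest",
    "DemingFit",
    "hypergeom_overlap",
    "correlate",
    "deming_fit",
    "attribute_effect",
    "set_enrichment",
]


@dataclass
class OverlapTest:
    N: int
    K: int
    n: int
    k: int
    p: float

    @property
    def fraction(self) -> float:
        return self.k / self.n if self.n else np.nan


@dataclass
class DemingFit:
    slope: float
    intercept: float
    r: float
    r2: float
    n: int
    converged: bool = True


def hypergeom_overlap(N: int, K: int, n: int, k: int) -> OverlapTest:
    """Upper-tail hypergeometric test of an overlap of k between sets of
    size K and n drawn from a universe of N."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent overlap counts N={N}, K={K}, n={n}, k={k}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapTest(N=N, K=K, n=n, k=k, p=min(p, 1.0))


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with its p-value.

    Raises on fewer than 3 points, non-finite input, or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("correlation needs at least 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Deming regression
# ---------------------------------------------------------------------------

def _deming_closed_form(x, y, delta: float = 1.0) -> tuple[float, float]:
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    syy = ((y - ybar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    if sxy == 0:
        raise ValueError("S_xy = 0: Deming fit degenerate (vertical or undefined)")
    slope = (syy - delta * sxx + np.sqrt((syy - delta * sxx) ** 2 + 4 * delta * sxy**2)) / (
        2 * sxy
    )
    return slope, ybar - slope * xbar


def deming_fit(
    x,
    y,
    sx=None,
    sy=None,
    weighted: bool = False,
    delta: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> DemingFit:
    """Errors-in-variables straight-line fit.

    Unweighted: closed-form Deming estimator with error-variance ratio
    ``delta`` (default 1, i.e. orthogonal regression). Weighted: per-point
    standard errors ``sx``/``sy`` enter an iteratively reweighted scheme
    (York-style) minimizing the total weighted orthogonal squared distance

        sum_i (y_i - a - b x_i)^2 / (sy_i^2 + b^2 sx_i^2),

    iterated until the slope changes by less than ``tol`` (at most
    ``max_iter`` passes). ``r`` is the Pearson correlation of the fitted
    pair and ``r2`` its square.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("Deming fit needs at least 3 points")
    r, _ = (np.corrcoef(x, y)[0, 1], None) if np.std(x) > 0 and np.std(y) > 0 else (np.nan, None)
    if not weighted:
        slope, intercept = _deming_closed_form(x, y, delta=delta)
        return DemingFit(float(slope), float(intercept), float(r), float(r) ** 2, x.size)
    sx = np.asarray(sx, dtype=float)
    sy = np.asarray(sy, dtype=float)
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("weighted Deming requires positive per-point errors")
    slope, _ = _deming_closed_form(x, y, delta=1.0)
    converged = False
    for _ in range(max_iter):
        w = 1.0 / (sy**2 + slope**2 * sx**2)
        xw = np.sum(w * x) / np.sum(w)
        yw = np.sum(w * y) / np.sum(w)
        U = x - xw
        V = y - yw
        # York update: beta_i carries each point's leverage along the line
        beta_i = w * (U * sy**2 + slope * V * sx**2)
        denom = np.sum(w * beta_i * U)
        if denom == 0:
            raise ValueError("degenerate weighted Deming fit")
        new_slope = np.sum(w * beta_i * V) / denom
        if abs(new_slope - slope) < tol:
            slope = new_slope
            converged = True
            break
        slope = new_slope
    w = 1.0 / (sy**2 + slope**2 * sx**2)
    intercept = np.sum(w * (y - slope * x)) / np.sum(w)
    return DemingFit(float(slope), float(intercept), float(r), float(r) ** 2, x.size, converged)


# ---------------------------------------------------------------------------
# knockdown attribution
# ---------------------------------------------------------------------------

def attribute_effect(pairs: pd.DataFrame) -> dict:
    """Attribute copy-number responses to a knockdown response.

    ``pairs`` carries per-gene columns ``beta_chr``/``se_chr`` (log2FC per
    chromosome copy) and ``beta_kd``/``se_kd`` (log2FC upon knockdown of the
    candidate regulator). Since knocking down an activator mirrors removing
    a chromosome copy, the knockdown response is negated and regressed
    against the copy-number response with a weighted Deming fit.

    Returns the Deming r^2 (the headline "fraction of effects explained"),
    the fit itself, and per-gene effect ratios
    100 * clip(-beta_kd / beta_chr, 0, 1) with their quartiles as the
    secondary, per-gene reading of "percent explained".
    """
    if len(pairs) == 0:
        raise ValueError("empty significant gene set for attribution")
    x = pairs["beta_chr"].to_numpy(dtype=float)
    y = -pairs["beta_kd"].to_numpy(dtype=float)
    fit = deming_fit(
        x,
        y,
        sx=pairs["se_chr"].to_numpy(dtype=float),
        sy=pairs["se_kd"].to_numpy(dtype=float),
        weighted=True,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(x != 0, y / x, np.nan)
    percent = 100.0 * np.clip(ratio, 0.0, 1.0)
    q25, q50, q75 = np.nanpercentile(percent, [25, 50, 75])
    return {
        "r2": fit.r2,
        "fit": fit,
        "percent_explained": pd.Series(percent, index=pairs.index),
        "percent_quartiles": (float(q25), float(q50), float(q75)),
    }


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------

def set_enrichment(
    target: set | list,
    background: set | list,
    collections: dict[str, set] | dict[str, list],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``target`` within gene-set collections.

    Memberships are restricted to ``background`` (the expressed genes of the
    relevant cell type) before testing; BH across sets. ``target`` must be a
    subset of ``background``.
    """
    target = set(target)
    background = set(background)
    if not target <= background:
        raise ValueError("target set must be a subset of the background")
    N, n = len(background), len(target)
    rows = []
    for name, members in collections.items():
        mem = set(members) & background
        if not mem:
            continue
        k = len(mem & target)
        rows.append({"set": name, "set_size": len(mem), "overlap": k,
                     "p": hypergeom_overlap(N, len(mem), n, k).p})
    if not rows:
        raise ValueError("no collection intersects the background")
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = adjust_bh(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    return out.sort_values("p")
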