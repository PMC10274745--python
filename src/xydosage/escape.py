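"""Meta-analysis of Xi allelic-ratio studies into escape/subject calls.

Five published assays of X-inactivation escape report allelic ratios (AR:
reads from the lower-expressed Xi allele over the higher-expressed Xa
allele) in incompatible dialects — per-gene summaries, per-sample ratios,
active-X read fractions, skew-adjusted ratios, and precomputed adjusted
p-values. Each dialect gets a caller that applies that study's inclusion
rule and test, producing a per-gene verdict of ``escape`` (detectable Xi
expression), ``subject`` (silenced on Xi), or ``no_data``. The verdicts are
then combined by a deterministic majority-plus-evidence rule, with a
fallback to the fraction of human-rodent Xi-hybrid cell lines expressing a
gene when no study covers it.

All numeric thresholds live in :class:`EscapeThresholds` and default to the
published values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dosage import adjust_bh

ESCAPE = "escape"
SUBJECT = "subject"
NO_DATA = "no_data"
NO_CALL = "no_call"

STUDY_IDS = ["summaryAR", "precomputed", "singlecell_fraction", "skew_adjusted", "bulkAR"]

__all__ = [
    "EscapeThresholds",
    "ar_from_xa_fraction",
    "baseline_ar",
    "call_summary_ar_study",
    "call_per_sample_threshold_study",
    "call_skew_adjusted_study",
    "call_precomputed_study",
    "call_bulk_ar_study",
    "combine_calls",
    "classify_escape",
]


@dataclass
class EscapeThresholds:
    """Published constants of the meta-analysis, overridable for sensitivity checks."""

    summary_min_samples: int = 5
    summary_padj: float = 0.05
    per_sample_min_samples: int = 2
    per_sample_ar: float = 0.0526  # AR above which a single cell shows Xi expression
    skew_min_samples: int = 10
    skew_padj: float = 0.01
    precomputed_padj: float = 0.05
    bulk_min_samples: int = 2
    bulk_padj: float = 0.05
    mean_ar_cut: float = 0.1
    hybrid_escape_fraction: float = 0.22
    # the hybrid rule is stated only in the escape direction; by default
    # hybrid evidence below the cut counts as subject, set to False to
    # leave such genes uncalled
    hybrid_below_is_subject: bool = True


# ---------------------------------------------------------------------------
# elementary conversions
# ---------------------------------------------------------------------------

def ar_from_xa_fraction(f) -> float | np.ndarray:
    """Convert an active-X read fraction (Xa reads / total reads) to an AR.

    AR = 1/f - 1: f = 1 means fully monoallelic (AR 0), f = 0.5 means
    balanced biallelic expression (AR 1).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or np.any(f > 1):
        raise ValueError("Xa fraction must lie in (0, 1]")
    out = 1.0 / f - 1.0
    return float(out) if out.ndim == 0 else out


def baseline_ar(skew) -> float | np.ndarray:
    """Expected AR under complete Xi silencing given a skewing coefficient.

    With a fraction ``skew`` of cells inactivating the same parental X, a
    fully silenced gene still shows AR = (1 - skew)/skew from the minority
    cell population.
    """
    skew = np.asarray(skew, dtype=float)
    if np.any(skew <= 0.5) or np.any(skew > 1):
        raise ValueError("skewing coefficient must lie in (0.5, 1]")
    out = (1.0 - skew) / skew
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# per-study callers
# ---------------------------------------------------------------------------

def _calls_frame(gene_ids, call, mean_ar) -> pd.DataFrame:
    return pd.DataFrame({"call": call, "mean_AR": mean_ar}, index=pd.Index(gene_ids, name="gene_id"))


def call_summary_ar_study(
    records: pd.DataFrame,
    thresholds: EscapeThresholds | None = None,
    min_samples: int | None = None,
    padj_threshold: float | None = None,
) -> pd.DataFrame:
    """Caller for per-gene summary statistics (mean AR, SD, n informative).

    Genes informative in at least ``min_samples`` samples are tested with a
    one-sample, one-sided t-test of mean AR > 0 (t = mean/(sd/sqrt(n)),
    df = n - 1); BH across included genes; escape below the adjusted-p
    threshold. A degenerate sd of 0 with positive mean yields p = 0.
    """
    th = thresholds or EscapeThresholds()
    min_n = th.summary_min_samples if min_samples is None else min_samples
    cut = th.summary_padj if padj_threshold is None else padj_threshold
    rec = records.set_index("gene_id") if "gene_id" in records.columns else records
    mean = rec["mean_ar"].to_numpy(dtype=float)
    sd = rec["sd_ar"].to_numpy(dtype=float)
    n = rec["n_informative"].to_numpy(dtype=float)
    included = n >= min_n
    p = np.full(len(rec), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    for i in np.flatnonzero(included):
        if sd[i] == 0:
            p[i] = 0.0 if mean[i] > 0 else 0.5
        else:
            p[i] = stats.t.sf(t[i], df=n[i] - 1)
    padj = adjust_bh(p)
    call = np.where(~included, NO_DATA, np.where(padj < cut, ESCAPE, SUBJECT))
    mean_ar = np.where(included, mean, np.nan)
    return _calls_frame(rec.index, call, mean_ar)


def call_per_sample_threshold_study(
    records: pd.DataFrame, thresholds: EscapeThresholds | None = None
) -> pd.DataFrame:
    """Caller for per-sample single-cell ARs with a fixed escape threshold.

    ``records`` is long-form with columns ``gene_id``, ``sample_id`` and
    either ``ar`` or ``xa_fraction`` (converted via
    :func:`ar_from_xa_fraction`). Genes with data from at least two samples
    are included; escape if any single sample exceeds the AR threshold
    (strictly).
    """
    th = thresholds or EscapeThresholds()
    rec = records.copy()
    if "ar" not in rec.columns:
        rec["ar"] = ar_from_xa_fraction(rec["xa_fraction"].to_numpy(dtype=float))
    grouped = rec.groupby("gene_id")["ar"]
    n = grouped.size()
    any_escape = grouped.max() > th.per_sample_ar
    mean_ar = grouped.mean()
    included = n >= th.per_sample_min_samples
    call = np.where(~included, NO_DATA, np.where(any_escape, ESCAPE, SUBJECT))
    return _calls_frame(n.index, call, np.where(included, mean_ar, np.nan))


def call_skew_adjusted_study(
    records: pd.DataFrame, thresholds: EscapeThresholds | None = None
) -> pd.DataFrame:
    """Caller for skew-aware bulk ARs (paired test against the baseline AR).

    ``records`` is long-form with columns ``gene_id``, ``sample_id``,
    ``skew`` and either ``ar`` or allele counts ``a_low``/``a_high``.
    Samples with skew <= 0.5 are uninformative and dropped. Genes with at
    least ten informative samples are tested with a paired, one-sided t-test
    of (raw AR - baseline AR) > 0; BH; escape below the adjusted-p cut.
    """
    th = thresholds or EscapeThresholds()
    rec = records.copy()
    if "ar" not in rec.columns:
        high = rec["a_high"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rec["ar"] = np.where(high > 0, rec["a_low"].to_numpy(dtype=float) / high, np.nan)
    rec = rec[rec["skew"] > 0.5]
    gene_ids = records["gene_id"].unique()
    if len(rec) == 0:
        return _calls_frame(gene_ids, NO_DATA, np.nan)
    rec = rec.dropna(subset=["ar"])
    rec["d"] = rec["ar"].to_numpy(dtype=float) - baseline_ar(rec["skew"].to_numpy(dtype=float))
    # skew-adjusted AR: the excess over baseline, clipped at zero
    rec["ar_adj"] = np.clip(rec["d"], 0.0, None)
    g = rec.groupby("gene_id")
    n = g["d"].size().reindex(gene_ids, fill_value=0)
    included = n >= th.skew_min_samples
    p = pd.Series(np.nan, index=pd.Index(gene_ids, name="gene_id"))
    for gene in n.index[included]:
        d = g.get_group(gene)["d"].to_numpy(dtype=float)
        if np.allclose(d, 0.0) or np.std(d, ddof=1) == 0:
            p[gene] = 0.5 if np.allclose(d, 0.0) else (0.0 if d.mean() > 0 else 1.0)
        else:
            t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            p[gene] = stats.t.sf(t, df=len(d) - 1)
    padj = pd.Series(adjust_bh(p.to_numpy()), index=p.index)
    mean_ar = g["ar_adj"].mean().reindex(gene_ids)
    call = np.where(~included, NO_DATA, np.where(padj < th.skew_padj, ESCAPE, SUBJECT))
    return _calls_frame(gene_ids, call, np.where(included, mean_ar, np.nan))


def call_precomputed_study(
    records: pd.DataFrame, thresholds: EscapeThresholds | None = None
) -> pd.DataFrame:
    """Caller for a two-arm study with precomputed adjusted p-values.

    Columns: ``gene_id``, ``n_singlecell_individuals``, ``has_bulk``
    (bool), ``padj_singlecell``, ``padj_bulk``, optional ``mean_ar``.
    Included if the single-cell arm covers at least two individuals, or one
    individual plus bulk data. Escape if any included arm's adjusted p is
    below the threshold (OR rule — escape wins on disagreement).
    """
    th = thresholds or EscapeThresholds()
    rec = records.set_index("gene_id") if "gene_id" in records.columns else records
    n_sc = rec["n_singlecell_individuals"].to_numpy(dtype=float)
    has_bulk = rec["has_bulk"].to_numpy(dtype=bool)
    included = (n_sc >= 2) | ((n_sc == 1) & has_bulk)
    p_sc = rec["padj_singlecell"].to_numpy(dtype=float)
    p_bulk = rec["padj_bulk"].to_numpy(dtype=float)
    esc_sc = (n_sc >= 1) & (p_sc < th.precomputed_padj)
    esc_bulk = has_bulk & (p_bulk < th.precomputed_padj)
    call = np.where(~included, NO_DATA, np.where(esc_sc | esc_bulk, ESCAPE, SUBJECT))
    mean_ar = rec["mean_ar"].to_numpy(dtype=float) if "mean_ar" in rec.columns else np.full(len(rec), np.nan)
    return _calls_frame(rec.index, call, np.where(included, mean_ar, np.nan))


def call_bulk_ar_study(
    records: pd.DataFrame, thresholds: EscapeThresholds | None = None
) -> pd.DataFrame:
    """Caller for per-sample bulk ARs tested against zero.

    Long-form columns ``gene_id``, ``sample_id``, ``ar``. Per-sample ARs
    are summarised to (mean, sd, n) and passed through the one-sample
    one-sided t machinery; genes need at least two samples for a defined
    test.
    """
    th = thresholds or EscapeThresholds()
    g = records.groupby("gene_id")["ar"]
    summary = pd.DataFrame(
        {"mean_ar": g.mean(), "sd_ar": g.std(ddof=1).fillna(0.0), "n_informative": g.size()}
    ).reset_index()
    return call_summary_ar_study(
        summary, thresholds=th, min_samples=th.bulk_min_samples, padj_threshold=th.bulk_padj
    )


# ---------------------------------------------------------------------------
# combining
# ---------------------------------------------------------------------------

def combine_calls(
    study_calls: pd.DataFrame,
    hybrid_fraction: pd.Series | None = None,
    thresholds: EscapeThresholds | None = None,
) -> pd.DataFrame:
    """Combine per-study verdicts into a final three-way classification.

    ``study_calls`` is indexed by gene with one ``call_<study>`` column per
    study (values escape/subject/no_data) and one ``mean_AR_<study>``
    column per study (NaN when that study reports no AR for the gene).

    Escape if more than half of the data-bearing studies say escape; or if
    at most half (but at least one) do and either more than one study shows
    escape or the cross-study mean AR is >= 0.1. Subject if every
    data-bearing study says subject, or more than half do and the mean AR
    is < 0.1. Genes with no study data fall back to the Xi-hybrid panel:
    escape when expressed in at least 22% of hybrid lines, otherwise
    subject (configurable) or no_call when the panel is silent too.
    """
    th = thresholds or EscapeThresholds()
    call_cols = [c for c in study_calls.columns if c.startswith("call_")]
    ar_cols = [c for c in study_calls.columns if c.startswith("mean_AR_")]
    calls = study_calls[call_cols].to_numpy(dtype=object)
    ars = study_calls[ar_cols].to_numpy(dtype=float) if ar_cols else np.full((len(study_calls), 0), np.nan)

    n_escape = (calls == ESCAPE).sum(axis=1)
    n_subject = (calls == SUBJECT).sum(axis=1)
    n_data = n_escape + n_subject
    finite = np.isfinite(ars)
    n_ar = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_ar = np.where(n_ar > 0, np.where(finite, ars, 0.0).sum(axis=1) / np.maximum(n_ar, 1), np.nan)
    ar_high = np.nan_to_num(mean_ar, nan=0.0) >= th.mean_ar_cut

    final = np.full(len(study_calls), NO_CALL, dtype=object)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_escape = np.where(n_data > 0, n_escape / np.maximum(n_data, 1), 0.0)
        frac_subject = np.where(n_data > 0, n_subject / np.maximum(n_data, 1), 0.0)
    has_data = n_data > 0
    esc_majority = has_data & (frac_escape > 0.5)
    esc_minority = has_data & (frac_escape <= 0.5) & (n_escape > 0) & ((n_escape > 1) | ar_high)
    sub_all = has_data & (n_escape == 0)
    sub_majority = has_data & (frac_subject > 0.5) & ~ar_high
    final[esc_majority | esc_minority] = ESCAPE
    mask_sub = (sub_all | sub_majority) & ~(esc_majority | esc_minority)
    final[mask_sub] = SUBJECT

    hybrid = (
        hybrid_fraction.reindex(study_calls.index)
        if hybrid_fraction is not None
        else pd.Series(np.nan, index=study_calls.index)
    )
    hv = hybrid.to_numpy(dtype=float)
    no_study = ~has_data
    final[no_study & (hv >= th.hybrid_escape_fraction)] = ESCAPE
    if th.hybrid_below_is_subject:
        final[no_study & np.isfinite(hv) & (hv < th.hybrid_escape_fraction)] = SUBJECT

    out = study_calls.copy()
    out["n_escape"] = n_escape
    out["n_subject"] = n_subject
    out["n_with_data"] = n_data
    out["mean_AR"] = mean_ar
    out["hybrid_fraction"] = hv
    out["final"] = final
    return out


def classify_escape(
    studies: dict[str, pd.DataFrame],
    hybrid_fraction: pd.Series | None = None,
    thresholds: EscapeThresholds | None = None,
) -> pd.DataFrame:
    """Run every dialect caller and combine the verdicts.

    ``studies`` maps study ids (a subset of ``STUDY_IDS``) to their
    dialect-specific tables.
    """
    th = thresholds or EscapeThresholds()
    callers = {
        "summaryAR": call_summary_ar_study,
        "precomputed": call_precomputed_study,
        "singlecell_fraction": call_per_sample_threshold_study,
        "skew_adjusted": call_skew_adjusted_study,
        "bulkAR": call_bulk_ar_study,
    }
    frames = {}
    for sid, table in studies.items():
        if sid not in callers:
            raise ValueError(f"unknown study dialect {sid!r}")
        frames[sid] = callers[sid](table, thresholds=th)
    genes = sorted(set().union(*[set(f.index) for f in frames.values()])) if frames else []
    if hybrid_fraction is not None:
        genes = sorted(set(genes) | set(hybrid_fraction.index))
    merged = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for sid in STUDY_IDS:
        if sid in frames:
            f = frames[sid].reindex(genes)
            merged[f"call_{sid}"] = f["call"].fillna(NO_DATA)
            merged[f"mean_AR_{sid}"] = f["mean_AR"]
        else:
            merged[f"call_{sid}"] = NO_DATA
            merged[f"mean_AR_{sid}"] = np.nan
    return combine_calls(merged, hybrid_fraction=hybrid_fraction, thresholds=th)
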