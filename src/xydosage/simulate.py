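"""Synthetic cohorts, allelic-ratio studies, and depth profiles with known truth.

Everything downstream consumes data of three shapes: gene x sample count
matrices from a karyotypically diverse cohort, per-study allelic-ratio
tables in five dialects, and per-sample binned read-depth profiles over the
DYZ1 satellite and a single-copy reference region. This module generates
all three with ground truth attached, reproducing the statistical structure
the analyses assume:

* counts are negative binomial with a log-linear mean in X / Y / Chr 21
  copy number plus batch offsets and log-normal library sizes;
* allelic ratios of escape genes concentrate away from zero while subject
  genes sit near zero, filtered through each study dialect's quirks
  (summaries, skewing, missingness, precomputed p-values);
* binned depths scale with true copy number, modulated by a smooth GC bias
  and multiplicative noise.

Defaults mirror the study conditions: a 120-sample cohort across nine
karyotypes from 45,X to 49,XYYYY, per-copy effect magnitudes below
1.5-fold, and DYZ1 copy numbers spanning roughly 20-900.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distributions import Law, draw

__all__ = [
    "SimCohortConfig",
    "SimTruth",
    "SimAllelicConfig",
    "simulate_cohort",
    "simulate_allelic_studies",
    "simulate_depth_profiles",
    "DEFAULT_KARYOTYPES",
]

# (x_copies, y_copies, chr21_copies, n_samples); fractional copies model mosaics
DEFAULT_KARYOTYPES: tuple = (
    (1, 0, 2, 10),
    (2, 0, 2, 30),
    (3, 0, 2, 10),
    (4, 0, 2, 5),
    (1, 1, 2, 30),
    (2, 1, 2, 10),
    (1, 2, 2, 15),
    (1, 3, 2, 5),
    (1, 4, 2, 5),
)


@dataclass
class SimCohortConfig:
    n_genes: int = 1000
    karyotype_table: Sequence = DEFAULT_KARYOTYPES
    frac_x_responsive: float = 0.05
    frac_y_responsive: float = 0.03
    frac_shared: float = 0.02
    frac_21_responsive: float = 0.0
    effect_size_law: Law = ("uniform_signed", 0.1, 0.6)
    baseline_law: Law = ("normal", 5.0, 2.0)
    dispersion_law: Law = ("lognormal", np.log(0.05), 0.5)
    n_batches: int = 3
    batch_sd: float = 0.1
    library_size_law: Law = ("lognormal", 0.0, 0.3)
    cell_type: str = "LCL"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.karyotype_table:
            raise ValueError("karyotype_table must not be empty")
        fr = self.frac_x_responsive + self.frac_y_responsive + self.frac_shared + self.frac_21_responsive
        if not 0 <= fr <= 1:
            raise ValueError("responsive-class fractions must sum to at most 1")
        for x, y, c, n in self.karyotype_table:
            if x < 1 or y < 0 or c < 0 or n < 1:
                raise ValueError("karyotype rows need x>=1 (one active X), y>=0, n>=1")
        if self.batch_sd < 0 or self.n_batches < 1:
            raise ValueError("batch structure misconfigured")


@dataclass
class SimTruth:
    beta0: pd.Series
    betaX: pd.Series
    betaY: pd.Series
    beta21: pd.Series
    alpha: pd.Series
    batch_offsets: pd.DataFrame       # genes x batches, log2 units
    library_size: pd.Series           # per sample
    truth_class: pd.Series            # null / x / y / shared / chr21

    @property
    def responsive_x(self) -> pd.Index:
        return self.betaX.index[self.betaX != 0]

    @property
    def responsive_y(self) -> pd.Index:
        return self.betaY.index[self.betaY != 0]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, variance = mu + alpha mu^2) via the gamma-Poisson mixture;
    alpha below 1e-10 degrades gracefully to Poisson."""
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = alpha < 1e-10
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        a = alpha[~tiny]
        lam = rng.gamma(shape=1.0 / a, scale=a * mean[~tiny])
        out[~tiny] = rng.poisson(lam)
    return out


def simulate_cohort(config: SimCohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (counts, sample sheet, truth) for a karyotype cohort.

    Counts follow NB(mean = libsize_s * 2^(b0 + bX x_s + bY y_s + b21 c_s +
    batch offset), dispersion alpha_g). Identical config and seed give
    byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    genes = pd.Index([f"gene{i:05d}" for i in range(G)], name="gene_id")

    # disjoint truth classes
    classes = np.array(["null"] * G, dtype=object)
    n_x = int(round(config.frac_x_responsive * G))
    n_y = int(round(config.frac_y_responsive * G))
    n_sh = int(round(config.frac_shared * G))
    n_21 = int(round(config.frac_21_responsive * G))
    perm = rng.permutation(G)
    pos = 0
    for label, n_class in (("x", n_x), ("y", n_y), ("shared", n_sh), ("chr21", n_21)):
        classes[perm[pos : pos + n_class]] = label
        pos += n_class

    beta0 = draw(config.baseline_law, G, rng)
    betaX = np.zeros(G)
    betaY = np.zeros(G)
    beta21 = np.zeros(G)
    for i in range(G):
        if classes[i] == "x":
            betaX[i] = draw(config.effect_size_law, 1, rng)[0]
        elif classes[i] == "y":
            betaY[i] = draw(config.effect_size_law, 1, rng)[0]
        elif classes[i] == "shared":
            bx = draw(config.effect_size_law, 1, rng)[0]
            by = draw(config.effect_size_law, 1, rng)[0]
            betaX[i] = bx
            betaY[i] = np.sign(bx) * abs(by)  # shared mechanism: same polarity
        elif classes[i] == "chr21":
            beta21[i] = draw(config.effect_size_law, 1, rng)[0]
    alpha = np.maximum(draw(config.dispersion_law, G, rng), 0.0)
    batch_offsets = rng.normal(0.0, config.batch_sd, size=(G, config.n_batches))
    batch_offsets[:, 0] = 0.0  # reference batch

    rows = []
    for x, y, c, n in config.karyotype_table:
        for _ in range(int(n)):
            rows.append((float(x), float(y), float(c)))
    S = len(rows)
    sample_ids = pd.Index([f"sample{i:04d}" for i in range(S)], name="sample_id")
    xs = np.array([r[0] for r in rows])
    ys = np.array([r[1] for r in rows])
    cs = np.array([r[2] for r in rows])
    batches = rng.integers(0, config.n_batches, size=S)
    libsize = draw(config.library_size_law, S, rng)

    log2_mu = (
        beta0[:, None]
        + betaX[:, None] * xs[None, :]
        + betaY[:, None] * ys[None, :]
        + beta21[:, None] * cs[None, :]
        + batch_offsets[:, batches]
    )
    mean = libsize[None, :] * np.exp2(log2_mu)
    counts = _nb_draw(rng, mean, np.broadcast_to(alpha[:, None], mean.shape))
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)

    samples = pd.DataFrame(
        {
            "cell_type": config.cell_type,
            "x_copies": xs,
            "y_copies": ys,
            "chr21_copies": cs,
            "batch": [f"batch{b}" for b in batches],
            "condition": "none",
            "group_label": [f"{int(x + y + 44)},{'X' * int(round(x))}{'Y' * int(round(y))}" for x, y in zip(xs, ys)],
        },
        index=sample_ids,
    )
    truth = SimTruth(
        beta0=pd.Series(beta0, index=genes, name="beta0"),
        betaX=pd.Series(betaX, index=genes, name="betaX"),
        betaY=pd.Series(betaY, index=genes, name="betaY"),
        beta21=pd.Series(beta21, index=genes, name="beta21"),
        alpha=pd.Series(alpha, index=genes, name="alpha"),
        batch_offsets=pd.DataFrame(
            batch_offsets, index=genes, columns=[f"batch{b}" for b in range(config.n_batches)]
        ),
        library_size=pd.Series(libsize, index=sample_ids, name="library_size"),
        truth_class=pd.Series(classes, index=genes, name="truth_class"),
    )
    return counts_df, samples, truth


# ---------------------------------------------------------------------------
# allelic-ratio studies
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    n_samples: int
    missingness: float = 0.1
    noise_sd: float = 0.03


@dataclass
class SimAllelicConfig:
    n_genes: int = 500
    frac_escape: float = 0.2
    true_escape_set: Sequence[str] | None = None
    ar_escape_law: Law = ("uniform", 0.15, 0.6)
    ar_subject_law: Law = ("exponential", 0.002)
    skew_law: Law = ("uniform", 0.7, 0.999)
    study_designs: dict = field(
        default_factory=lambda: {
            "summaryAR": StudyDesign(n_samples=20, missingness=0.15),
            "precomputed": StudyDesign(n_samples=3, missingness=0.25),
            "singlecell_fraction": StudyDesign(n_samples=5, missingness=0.3),
            "skew_adjusted": StudyDesign(n_samples=40, missingness=0.5),
            "bulkAR": StudyDesign(n_samples=10, missingness=0.3),
        }
    )
    detection_power: float = 0.95
    seed: int = 0


def simulate_allelic_studies(config: SimAllelicConfig) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Generate the five allelic-ratio study tables and truth labels.

    Escape genes draw a true Xi/Xa expression ratio from ``ar_escape_law``
    (strictly positive mass), subject genes from ``ar_subject_law``
    (concentrated near zero). Each study dialect then observes noisy,
    partially missing versions of that truth in its own format. Returns
    (tables keyed by study id, truth labels 'escape'/'subject').
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    genes = pd.Index([f"xgene{i:04d}" for i in range(G)], name="gene_id")
    if config.true_escape_set is not None:
        is_escape = genes.isin(set(config.true_escape_set))
    else:
        is_escape = np.zeros(G, dtype=bool)
        n_esc = int(round(config.frac_escape * G))
        is_escape[rng.permutation(G)[:n_esc]] = True
    true_ar = np.where(
        is_escape,
        np.clip(draw(config.ar_escape_law, G, rng), 0.0, 1.0),
        np.clip(draw(config.ar_subject_law, G, rng), 0.0, 1.0),
    )
    labels = pd.Series(np.where(is_escape, "escape", "subject"), index=genes, name="truth")
    tables: dict[str, pd.DataFrame] = {}

    def observed(n: int, true_ar: float, _sd: float) -> np.ndarray:
        # allelic ratios are read-count ratios: sample minor-allele reads
        # binomially so that silenced genes mostly report exactly zero
        total = rng.integers(40, 200, size=n)
        low = rng.binomial(total, true_ar / (1.0 + true_ar))
        return np.clip(low / np.maximum(total - low, 1), 0.0, 1.0)

    # study 1: per-gene mean AR, SD, n informative
    d = config.study_designs["summaryAR"]
    n_inf = rng.integers(2, d.n_samples + 1, size=G)
    rows = []
    for i, g in enumerate(genes):
        if rng.random() < d.missingness:
            continue
        vals = observed(int(n_inf[i]), true_ar[i], d.noise_sd)
        rows.append(
            {"gene_id": g, "mean_ar": vals.mean(), "sd_ar": vals.std(ddof=1), "n_informative": len(vals)}
        )
    tables["summaryAR"] = pd.DataFrame(rows)

    # study 2: two arms with precomputed adjusted p-values
    d = config.study_designs["precomputed"]
    rows = []
    for i, g in enumerate(genes):
        if rng.random() < d.missingness:
            continue
        n_sc = int(rng.integers(0, d.n_samples + 1))
        has_bulk = bool(rng.random() < 0.6)
        if n_sc == 0 and not has_bulk:
            continue
        detected = is_escape[i] and rng.random() < config.detection_power
        padj_sc = rng.uniform(0.0, 0.04) if (detected and n_sc > 0) else rng.uniform(0.06, 1.0)
        padj_bulk = rng.uniform(0.0, 0.04) if (detected and has_bulk) else rng.uniform(0.06, 1.0)
        rows.append(
            {
                "gene_id": g,
                "n_singlecell_individuals": n_sc,
                "has_bulk": has_bulk,
                "padj_singlecell": padj_sc if n_sc > 0 else np.nan,
                "padj_bulk": padj_bulk if has_bulk else np.nan,
                "mean_ar": float(np.clip(true_ar[i] + rng.normal(0, d.noise_sd), 0, 1)),
            }
        )
    tables["precomputed"] = pd.DataFrame(rows)

    # study 3: per-sample active-X read fractions from single cells
    d = config.study_designs["singlecell_fraction"]
    rows = []
    for i, g in enumerate(genes):
        for s in range(d.n_samples):
            if rng.random() < d.missingness:
                continue
            ar = float(observed(1, true_ar[i], d.noise_sd)[0])
            rows.append(
                {"gene_id": g, "sample_id": f"sc{s}", "xa_fraction": 1.0 / (1.0 + ar)}
            )
    tables["singlecell_fraction"] = pd.DataFrame(rows)

    # study 4: per-sample allele counts in skewed bulk samples
    d = config.study_designs["skew_adjusted"]
    skews = np.clip(draw(config.skew_law, d.n_samples, rng), 0.5 + 1e-9, 1.0)
    rows = []
    for i, g in enumerate(genes):
        for s in range(d.n_samples):
            if rng.random() < d.missingness:
                continue
            # counting noise below comes from the binomial draw itself
            base = (1.0 - skews[s]) / skews[s]
            raw_ar = float(np.clip(base + true_ar[i], 0.0, 1.0))
            total = int(rng.integers(40, 200))
            a_low = int(rng.binomial(total, raw_ar / (1.0 + raw_ar)))
            rows.append(
                {
                    "gene_id": g,
                    "sample_id": f"bulk{s}",
                    "a_low": a_low,
                    "a_high": total - a_low,
                    "skew": skews[s],
                }
            )
    tables["skew_adjusted"] = pd.DataFrame(rows)

    # study 5: per-sample ARs from skewed bulk RNA-seq
    d = config.study_designs["bulkAR"]
    rows = []
    for i, g in enumerate(genes):
        for s in range(d.n_samples):
            if rng.random() < d.missingness:
                continue
            rows.append(
                {"gene_id": g, "sample_id": f"ar{s}", "ar": float(observed(1, true_ar[i], d.noise_sd)[0])}
            )
    tables["bulkAR"] = pd.DataFrame(rows)
    return tables, labels


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------

def simulate_depth_profiles(
    n_samples: int,
    copy_law: Law = ("uniform", 20.0, 900.0),
    gc_bias_amplitude: float = 0.3,
    noise_sd: float = 0.05,
    base_depth: float = 2.0,
    n_bins_dyz1: int = 60,
    n_bins_single: int = 120,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Binned depth tables over DYZ1 and a single-copy region, with truth.

    Per-bin depth = base_depth * copy_number * bias(GC) * noise, with
    bias(gc) = 1 + amplitude * sin(2 pi (gc - 0.5)) and log-normal
    multiplicative noise. Single-copy bins have copy number 1; DYZ1 bins
    share the sample's true copy number drawn from ``copy_law``. DYZ1 GC
    content runs higher than the single-copy region, so an uncorrected
    ratio inherits the GC bias. Returns (long-form table, true copies).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    if gc_bias_amplitude < 0:
        raise ValueError("gc_bias_amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    copies = np.maximum(draw(copy_law, n_samples, rng), 0.0)
    rows = []
    sample_ids = [f"wgs{i:04d}" for i in range(n_samples)]
    for i, sid in enumerate(sample_ids):
        depth_scale = base_depth * rng.lognormal(0.0, 0.2)
        gc_sc = rng.uniform(0.30, 0.70, n_bins_single)
        gc_dyz = rng.uniform(0.50, 0.72, n_bins_dyz1)
        for region, gcs, copy in (("single_copy", gc_sc, 1.0), ("DYZ1", gc_dyz, copies[i])):
            bias = 1.0 + gc_bias_amplitude * np.sin(2.0 * np.pi * (gcs - 0.5))
            noise = rng.lognormal(0.0, noise_sd, len(gcs)) if noise_sd > 0 else 1.0
            depth = depth_scale * copy * bias * noise
            for b, (gc, dep) in enumerate(zip(gcs, depth)):
                rows.append(
                    {"sample_id": sid, "bin_id": f"{region}_{b}", "region": region,
                     "gc_fraction": gc, "depth": dep}
                )
    table = pd.DataFrame(rows)
    return table, pd.Series(copies, index=pd.Index(sample_ids, name="sample_id"), name="true_copies")
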