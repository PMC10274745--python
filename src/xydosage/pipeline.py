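"""End-to-end orchestration: filter, normalize, fit, compare, classify.

`run_pipeline` ties the stages together on files referenced by a
:class:`PipelineConfig` (constructible from YAML), writes per-covariate
result TSVs plus a JSON manifest carrying the seed, package versions, and
SHA-256 checksums of every input, and returns the in-memory results bundle.
Reruns with identical inputs and seed produce identical result files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import deming_fit, hypergeom_overlap
from .dosage import build_design, compute_size_factors, compute_tpm, filter_expressed, fit_dosage_model
from .escape import EscapeThresholds, classify_escape
from .io import (
    read_count_matrix,
    read_gene_annotation,
    read_sample_sheet,
    read_study_table,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    counts: str
    samples: str
    annotation: str
    out_dir: str
    design: list = field(default_factory=lambda: ["x_copies", "y_copies", "batch"])
    covariates_of_interest: list = field(default_factory=lambda: ["x_copies", "y_copies"])
    cell_type: str | None = None
    tpm_threshold: float = 1.0
    padj_threshold: float = 0.05
    studies: dict | None = None          # study_id -> path
    hybrid_fractions: str | None = None  # TSV: gene_id, hybrid_fraction
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        for label, p in self.input_paths().items():
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if self.tpm_threshold <= 0 or self.padj_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def input_paths(self) -> dict[str, str]:
        paths = {"counts": self.counts, "samples": self.samples, "annotation": self.annotation}
        for sid, p in (self.studies or {}).items():
            paths[f"study:{sid}"] = p
        if self.hybrid_fractions:
            paths["hybrid_fractions"] = self.hybrid_fractions
        return paths


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute filter -> normalize -> fit -> overlap/Deming -> escape meta.

    Any stage failure aborts with the stage name in the exception message.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # re-raise with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    counts = stage("read_counts")(lambda: read_count_matrix(config.counts))
    samples = stage("read_samples")(lambda: read_sample_sheet(config.samples))
    annotation = stage("read_annotation")(lambda: read_gene_annotation(config.annotation))
    samples = samples.loc[counts.columns]
    if config.cell_type is not None:
        keep = samples.index[samples["cell_type"] == config.cell_type]
        samples = samples.loc[keep]
        counts = counts[keep]

    tpm = stage("tpm")(lambda: compute_tpm(counts, annotation))
    expressed = stage("filter")(
        lambda: filter_expressed(tpm, samples, threshold=config.tpm_threshold)
    )
    cell_types = list(expressed)
    fits = {}
    for ct in cell_types:
        genes = expressed[ct]
        sub = samples.index[samples["cell_type"] == ct]
        sub_counts = counts.loc[genes, sub]
        sf = stage(f"size_factors[{ct}]")(
            lambda sc=sub_counts: compute_size_factors(sc, allow_pseudo_reference=True)
        )
        design = stage(f"design[{ct}]")(
            lambda s=samples.loc[sub]: build_design(s, config.design)
        )
        fits[ct] = stage(f"fit[{ct}]")(
            lambda sc=sub_counts, s=samples.loc[sub], d=design, f=sf: fit_dosage_model(
                sc, s, d, size_factors=f, covariates_of_interest=config.covariates_of_interest
            )
        )
        for cov, table in fits[ct].tables.items():
            table.to_csv(out_dir / f"fit_{ct}_{cov}.tsv", sep="\t")
    results["fits"] = fits
    results["expressed"] = expressed

    # overlap and Deming comparison of the first two covariates of interest
    comparisons = {}
    for ct, fit in fits.items():
        covs = config.covariates_of_interest
        if len(covs) >= 2:
            a, b = covs[0], covs[1]
            sig_a = set(fit.significant(a, config.padj_threshold))
            sig_b = set(fit.significant(b, config.padj_threshold))
            universe = fit.tables[a].index
            both = sorted(sig_a & sig_b)
            comp = {
                "overlap": hypergeom_overlap(len(universe), len(sig_a), len(sig_b), len(sig_a & sig_b))
                if sig_a and sig_b
                else None,
            }
            if len(both) >= 3:
                ta, tb = fit.tables[a].loc[both], fit.tables[b].loc[both]
                comp["deming"] = deming_fit(
                    ta["log2FC"], tb["log2FC"], sx=ta["SE"], sy=tb["SE"], weighted=True
                )
            comparisons[ct] = comp
    results["comparisons"] = comparisons

    if config.studies:
        studies = {sid: read_study_table(p) for sid, p in config.studies.items()}
        hybrid = None
        if config.hybrid_fractions:
            hseries = pd.read_csv(config.hybrid_fractions, sep="\t", index_col="gene_id")
            hybrid = hseries["hybrid_fraction"]
        escape_calls = stage("escape_meta")(
            lambda: classify_escape(studies, hybrid_fraction=hybrid, thresholds=EscapeThresholds())
        )
        escape_calls.to_csv(out_dir / "escape_calls.tsv", sep="\t")
        results["escape_calls"] = escape_calls

    manifest = {
        "package": "xydosage",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "inputs": {label: _sha256(p) for label, p in config.input_paths().items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
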