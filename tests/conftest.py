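import numpy as np
import pandas as pd
import pytest

import xydosage as xd


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-gene, 120-sample cohort with planted X/Y effects."""
    cfg = xd.SimCohortConfig(n_genes=300, seed=11)
    counts, samples, truth = xd.simulate_cohort(cfg)
    return counts, samples, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    counts, samples, truth = small_cohort
    sf = xd.compute_size_factors(counts, allow_pseudo_reference=True)
    fit = xd.fit_dosage_model(
        counts, samples, ["x_copies", "y_copies", "batch"], size_factors=sf
    )
    return fit, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_annotation():
    return pd.DataFrame(
        {
            "chromosome": ["chr1", "chr1", "chr2"],
            "start": [1000, 5000, 100],
            "end": [3000, 8000, 900],
            "strand": ["+", "-", "+"],
            "effective_length": [1000, 2000, 800],
            "biotype": "protein_coding",
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
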