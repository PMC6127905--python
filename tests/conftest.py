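import numpy as np
import pandas as pd
import pytest

from plaquesig.io import CountMatrix, SampleTable
from plaquesig.simulate import ModuleSpec, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def lcm_cohort():
    """A small laser-capture-like cohort: 12 plaque vs 12 distal samples."""
    config = SimConfig.lcm_default(n_genes=1500, seed=11)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def null_cohort():
    """2,000 genes with zero effects in a 10 vs 10 two-group design."""
    config = SimConfig(
        n_genes=2000,
        design=(("TgCRND8", "TG", 6.0, "plaque_niche", 10),
                ("TgCRND8", "TG", 6.0, "non_plaque", 10)),
        modules={},
        dispersion=10.0,
        seed=5,
    )
    return simulate_cohort(config)


@pytest.fixture()
def tiny_samples():
    frame = pd.DataFrame({
        "sample_id": ["a1", "a2", "a3", "a4", "b1", "b2", "b3", "b4"],
        "strain": ["TgCRND8"] * 8,
        "genotype": ["TG"] * 8,
        "age_months": [6.0] * 8,
        "tissue_class": ["plaque_niche"] * 4 + ["non_plaque"] * 4,
    })
    return SampleTable(frame)


@pytest.fixture()
def tiny_counts(tiny_samples):
    genes = [f"g{i}" for i in range(6)]
    data = pd.DataFrame(
        np.arange(48).reshape(6, 8) * 3, index=genes,
        columns=tiny_samples.sample_ids)
    return CountMatrix(data)
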