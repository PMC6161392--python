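import numpy as np
import pandas as pd
import pytest

from clonecensus.synthetic import SimulationConfig, simulate_dataset
from clonecensus.types import FeatureTable


@pytest.fixture(scope="session")
def small_config():
    """A small but fully exercised simulation: 40 progenitors, 6 doublings,
    quadruplicate sampling at moderate depth."""
    return SimulationConfig(
        n_progenitors=40, divisions=6, per_division_loss=0.0,
        n_replicates=4, reads_per_replicate=800, seed=20240915,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def taxa_table():
    counts = pd.DataFrame(
        {
            "h1": [30, 5, 10, 0], "h2": [28, 6, 12, 1], "h3": [25, 4, 9, 0],
            "p1": [2, 40, 1, 30], "p2": [1, 38, 2, 28],
        },
        index=["Bacteroides", "Escherichia", "Lactobacillus", "Apicomplexa;Plasmodium"],
    )
    meta = pd.DataFrame(
        {
            "subject": ["H1", "H2", "H3", "P1", "P2"],
            "body_site": "stool",
            "timepoint_months": 0.0,
            "group": ["healthy", "healthy", "healthy", "patient", "patient"],
        },
        index=pd.Index(["h1", "h2", "h3", "p1", "p2"], name="sample_id"),
    )
    return FeatureTable(counts, meta)
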