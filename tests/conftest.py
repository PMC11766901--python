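import numpy as np
import pandas as pd
import pytest

import lesionflora as lf
from lesionflora.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture
def tiny_tables():
    """Three records over two lesions on one host."""
    metadata = pd.DataFrame({
        "sample_id": ["S1", "S2"],
        "tree_id": ["T1", "T1"],
        "host_species": ["Chamaerops humilis"] * 2,
        "parish": ["P1", "P1"],
        "lesion_type": ["TDB", "LLS"],
    })
    records = pd.DataFrame({
        "record_id": ["R1", "R2", "R3"],
        "sample_id": ["S1", "S1", "S2"],
        "genus": ["Alternaria", "Phoma", "Alternaria"],
        "motu_id": ["M1", "M2", "M1"],
        "gt_id": ["M1-GT1", "M2-GT1", "M1-GT1"],
        "assemblage_type": ["hyphomycete", "coelomycete", "hyphomycete"],
    })
    return records, metadata


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic survey reused across tests."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_matrix(default_dataset):
    d = default_dataset
    return lf.build_matrix(d["records"], d["metadata"], rank="motu")


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced survey (faster for pipeline-level tests)."""
    cfg = SimulationConfig(seed=5, n_hosts=4, samples_per_host=(12, 10, 8, 6),
                           total_records=600, alpha=40.0)
    return simulate_dataset(cfg)
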