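import numpy as np
import pandas as pd
import pytest

from rumensemble import CountTable, SimConfig, generate_cohort

SMALL_SHAPE = {"phylum": 4, "class": 6, "order": 8, "family": 12, "genus": 40}


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_cows=120, taxonomy_shape=dict(SMALL_SHAPE), seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """120 cows, 40 genera: shared across read-only tests."""
    return generate_cohort(small_config)


@pytest.fixture()
def toy_counts():
    """Hand-written 6-genus table over 2 phyla for exact collapse checks."""
    taxa = [f"g{i}" for i in range(1, 7)]
    counts = pd.DataFrame(
        [[3, 0, 5, 1],
         [2, 7, 0, 4],
         [0, 1, 9, 2],
         [8, 2, 1, 0],
         [1, 0, 0, 6],
         [4, 3, 2, 2]],
        index=pd.Index(taxa, name="taxon"),
        columns=["s1", "s2", "s3", "s4"], dtype=np.int64)
    lineages = pd.DataFrame({
        "phylum": ["P1", "P1", "P1", "P2", "P2", "P2"],
        "class": ["C1", "C1", "C2", "C3", "C3", "C3"],
        "order": ["O1", "O1", "O2", "O3", "O3", "O4"],
        "family": ["F1", "F2", "F3", "F4", "F4", "F5"],
        "genus": taxa,
    }, index=pd.Index(taxa, name="taxon"))
    return CountTable(counts, lineages)
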