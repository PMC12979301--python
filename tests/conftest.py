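import numpy as np
import pandas as pd
import pytest

import crcmicro as cm


@pytest.fixture(scope="session")
def small_config():
    return cm.SimulationConfig(
        n_participants=200, n_species=40, seed=123,
        depth_range=(5_000, 20_000))


@pytest.fixture(scope="session")
def small_cohort(small_config):
    pheno = cm.generate_phenotypes(small_config)
    scores = cm.compute_index(pheno)
    return pheno, scores


@pytest.fixture(scope="session")
def small_microbiome(small_config, small_cohort):
    pheno, scores = small_cohort
    table, tree, truth = cm.generate_microbiome(
        pheno, scores["total"].to_numpy(), small_config)
    return table, tree, truth


@pytest.fixture
def toy_counts():
    """Deterministic 4-sample, 3-taxon count table."""
    data = pd.DataFrame(
        [[10, 20, 30], [5, 5, 90], [40, 40, 20], [1, 0, 99]],
        index=["s1", "s2", "s3", "s4"], columns=["taxA", "taxB", "taxC"])
    return cm.FeatureTable(data, mode="counts")
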