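import pandas as pd
import pytest
from hypothesis import settings

import sector5 as s5

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config():
    """Small but structurally complete study: 6 nutrients x 6 rates."""
    return s5.SimulationConfig(n_genes=600, n_tfs=60, seed=11)


@pytest.fixture(scope="session")
def dataset_truth(config):
    return s5.generate_expression(config)


@pytest.fixture(scope="session")
def network(config, dataset_truth):
    _, truth = dataset_truth
    return s5.generate_network(config, truth)


@pytest.fixture(scope="session")
def fitted(config, dataset_truth):
    dataset, _ = dataset_truth
    est = s5.FiveSectorPartitioner(n_invariant=config.n_invariant_planted)
    return est.fit(dataset.raw, dataset.samples)


@pytest.fixture(scope="session")
def fractional(dataset_truth):
    dataset, _ = dataset_truth
    return s5.fractional_expression(dataset.raw)


def make_partition(labels: dict) -> s5.SectorPartition:
    """Partition from a gene -> sector mapping (evidence columns zeroed)."""
    ser = pd.Series(labels)
    table = pd.DataFrame(
        {
            "sector": ser,
            "n_nonspecific_pairs": 0,
            "n_invariant_nutrients": 0,
            "n_pos": 0,
            "n_neg": 0,
        }
    )
    return s5.SectorPartition(table)
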