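import numpy as np
import pytest

from trninfer import simulate
from trninfer.datatypes import (
    Contrast,
    CountMatrix,
    GeneRecord,
    RegulatoryAssociation,
    RegulonDB,
    SampleMeta,
)


@pytest.fixture(scope="session")
def small_truth():
    """A compact planted network shared by read-only tests."""
    return simulate.sample_truth(n_genes=400, n_middle=8, n_core=3,
                                 n_upstream=2, seed=11)


@pytest.fixture(scope="session")
def small_fit(small_truth):
    """One fitted model on the small truth, reused by read-only tests."""
    from trninfer.model import RegulatoryNetworkModel

    model = RegulatoryNetworkModel(
        counts=simulate.simulate_experiment(small_truth),
        regulon=simulate.emit_regulon(small_truth, seed=small_truth.seed),
        go_terms=simulate.truth_go_terms(small_truth),
        temperature_c=40.0,
    )
    return model.fit()


@pytest.fixture()
def toy_counts():
    """4 genes x 4 samples (WT and TF1 deletion, duplicates at 40 degC)."""
    genes = [
        GeneRecord("g1", 1000, False),
        GeneRecord("g2", 2000, False),
        GeneRecord("TF1", 1500, True),
        GeneRecord("g3", 500, False),
    ]
    samples = [
        SampleMeta("w1", "WT", 40.0, 1),
        SampleMeta("w2", "WT", 40.0, 2),
        SampleMeta("d1", "TF1", 40.0, 1),
        SampleMeta("d2", "TF1", 40.0, 2),
    ]
    counts = np.array([
        [100, 110, 95, 105],
        [50, 55, 200, 210],
        [80, 85, 0, 1],
        [0, 0, 0, 0],
    ])
    return CountMatrix(genes=genes, samples=samples, counts=counts)


@pytest.fixture()
def toy_regulon():
    return RegulonDB([
        RegulatoryAssociation("TF1", "g1"),
        RegulatoryAssociation("TF1", "g2", documented_sign="activation"),
        RegulatoryAssociation("TF2", "g1", documented_sign="inhibition"),
        RegulatoryAssociation("TF2", "TF1"),
    ])


@pytest.fixture()
def null_contrast():
    return Contrast("TF1", 40.0)
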