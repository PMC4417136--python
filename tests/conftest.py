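import numpy as np
import pandas as pd
import pytest

from rhizopart.io import OtuTable, SampleFrame, read_newick
from rhizopart.synth import ScenarioSpec, simulate_chemistry, simulate_sites, simulate_tree


@pytest.fixture
def tiny_otu_table() -> OtuTable:
    """Two subsamples of one sample, three OTUs."""
    idx = pd.MultiIndex.from_tuples(
        [("s1", "s1.a"), ("s1", "s1.b")], names=["sample_id", "subsample_id"]
    )
    return OtuTable(
        pd.DataFrame([[0.2, 0.8, 0.0], [0.4, 0.6, 0.0]],
                     index=idx, columns=["otu1", "otu2", "otu3"])
    )


@pytest.fixture
def three_tip_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def default_spec() -> ScenarioSpec:
    return ScenarioSpec(seed=11)


@pytest.fixture(scope="session")
def default_tree(default_spec):
    return simulate_tree(default_spec)


@pytest.fixture(scope="session")
def default_frame(default_spec) -> SampleFrame:
    return simulate_chemistry(simulate_sites(default_spec), default_spec)


def make_otu_table(matrix, sample_ids, subsample_ids, otu_ids) -> OtuTable:
    idx = pd.MultiIndex.from_arrays(
        [sample_ids, subsample_ids], names=["sample_id", "subsample_id"]
    )
    return OtuTable(pd.DataFrame(np.asarray(matrix, float), index=idx, columns=otu_ids))
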