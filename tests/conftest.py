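import pytest

from genehotel import isometry, netstats, phenograph, prisms


@pytest.fixture(scope="session")
def euclid():
    return isometry.euclidean_group()


@pytest.fixture(scope="session")
def sgc_graphs():
    return phenograph.code_graphs("sgc")


@pytest.fixture(scope="session")
def std_graphs():
    return phenograph.code_graphs("std-trna")


@pytest.fixture(scope="session")
def human_graphs():
    return phenograph.code_graphs("human-trna")


@pytest.fixture(scope="session")
def mean_tables(sgc_graphs, std_graphs, human_graphs):
    return {
        "sgc": netstats.mean_centrality(sgc_graphs),
        "std-trna": netstats.mean_centrality(std_graphs),
        "human-trna": netstats.mean_centrality(human_graphs),
    }


@pytest.fixture(scope="session")
def std_census():
    return prisms.prism_census("std-trna", induced=True)


@pytest.fixture(scope="session")
def human_census():
    return prisms.prism_census("human-trna", induced=True)
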