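import pytest

import dgconnect as dg
from dgconnect.drug_effect import annotations_from_frame, scores_from_frame


@pytest.fixture(scope="session")
def table5():
    return dg.load_fixture("table5_directionality")


@pytest.fixture(scope="session")
def table5_annotations(table5):
    return annotations_from_frame(table5)


@pytest.fixture(scope="session")
def table5_scores(table5):
    return scores_from_frame(table5)


@pytest.fixture(scope="session")
def luminal_a():
    return dg.load_fixture("luminalA_status")


@pytest.fixture(scope="session")
def basal():
    return dg.load_fixture("basal_status")


@pytest.fixture(scope="session")
def table3_records():
    return dg.load_fixture("table3_tamoxifen_esr1")


@pytest.fixture
def small_network():
    """Path graph a-b-c-d with mixed confidences."""
    return dg.WeightedNetwork.from_edges(
        [("a", "b", 0.9), ("b", "c", 0.8), ("c", "d", 0.7)]
    )
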