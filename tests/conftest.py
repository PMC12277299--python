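import numpy as np
import pytest
from hypothesis import settings

from anxclust import HierarchicalAnxietyModel, bundled_fixture, printed_partition

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def low_data():
    return bundled_fixture("table1_low")


@pytest.fixture(scope="session")
def high_data():
    return bundled_fixture("table2_high")


@pytest.fixture(scope="session")
def low_printed():
    return printed_partition("table1_low")


@pytest.fixture(scope="session")
def high_printed():
    return printed_partition("table2_high")


@pytest.fixture(scope="session")
def paired_table():
    return bundled_fixture("table3_paired")


@pytest.fixture(scope="session")
def low_model(low_data):
    return HierarchicalAnxietyModel(low_data, linkage="ward")


@pytest.fixture(scope="session")
def high_model(high_data):
    return HierarchicalAnxietyModel(high_data, linkage="ward")


@pytest.fixture()
def rng():
    return np.random.default_rng(20180901)
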