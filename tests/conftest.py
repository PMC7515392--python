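import pytest

from maxentpid import datasets


@pytest.fixture(scope="session")
def gates():
    return {name: datasets.gate(name) for name in datasets.GATE_NAMES}


@pytest.fixture(scope="session")
def random_binary_dists():
    """A pool of flat-Dirichlet all-binary joints used across tests."""
    return [datasets.random_joint((2, 2, 2, 2), seed=500 + i) for i in range(12)]
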