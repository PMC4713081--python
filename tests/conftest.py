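import pytest

from trnreduce.examples import hub_example_network
from trnreduce.network import Edge, Effect, NodeKind, RegulatoryNetwork


@pytest.fixture(scope="session")
def hub_network() -> RegulatoryNetwork:
    return hub_example_network()


@pytest.fixture
def tiny_network() -> RegulatoryNetwork:
    """1 TF regulating 2 TGs."""
    return RegulatoryNetwork(
        {"tfA": NodeKind.TF, "g1": NodeKind.TG, "g2": NodeKind.TG},
        [Edge("tfA", "g1", Effect.ACTIVATION), Edge("tfA", "g2", Effect.REPRESSION)],
    )
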