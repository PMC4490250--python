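import networkx as nx
import pytest

from locushub import build_graph
from locushub import io as io_mod


def fixture_graph(name: str) -> nx.MultiGraph:
    loci, edges = io_mod.load_worked_example(name)
    spatial = [e for e in edges if e.layer == "spatial"]
    eqtl = [e for e in edges if e.layer == "eqtl"]
    functional = [e for e in edges if e.layer == "functional"]
    return build_graph(spatial, eqtl, functional, loci)


@pytest.fixture
def tm6sf2_graph() -> nx.MultiGraph:
    """The transcribed three-way TM6SF2 / CTRB1-BCAR1 / CELSR2-PSRC1 hub."""
    return fixture_graph("tm6sf2_hub")


@pytest.fixture
def pank1_graph() -> nx.MultiGraph:
    """The direct PANK1-WFS1 connection."""
    return fixture_graph("pank1_wfs1")


@pytest.fixture
def grm5_graph() -> nx.MultiGraph:
    """IGF2BP2 and HNF1A sharing the GRM5 intermediary."""
    return fixture_graph("grm5_bridge")
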