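import networkx as nx
import pytest

from combonet.regnet_model import DrugActionProfile, RegEdge, build_network


@pytest.fixture
def chain_network():
    """A -> B -> C, both activations."""
    return build_network(
        [RegEdge("A", "B", "activation"), RegEdge("B", "C", "activation")]
    )


@pytest.fixture
def diamond_network():
    """A -> {B, C} -> D, all activations."""
    return build_network(
        [
            RegEdge("A", "B", "activation"),
            RegEdge("B", "D", "activation"),
            RegEdge("A", "C", "activation"),
            RegEdge("C", "D", "activation"),
        ]
    )


@pytest.fixture
def activator_profile():
    return DrugActionProfile("drugX", {"A": "activation"})


@pytest.fixture
def path5_graph():
    return nx.path_graph(["a", "b", "c", "d", "e"])


MINIMAL_KGML = """<?xml version="1.0"?>
<pathway name="path:test01" org="hsa" number="01">
  <entry id="1" name="hsa:10" type="gene"/>
  <entry id="2" name="hsa:20" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
</pathway>
"""


@pytest.fixture
def minimal_kgml():
    return MINIMAL_KGML
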