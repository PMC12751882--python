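"""Core data model: signed directed regulatory network and centrality screen.

Nodes are target identifiers (opaque, case-preserving strings; matching is
exact — ID mapping is the caller's concern). Edges carry a regulation label
from which the sign is derived: activation/expression are positive,
inhibition/repression negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: regulation label -> edge sign
RELATION_SIGNS: Mapping[str, int] = {
    "activation": +1,
    "expression": +1,
    "inhibition": -1,
    "repression": -1,
}

#: drug action label -> sign on the immediate target
ACTION_SIGNS: Mapping[str, int] = {
    "activation": +1,
    "upregulation": +1,
    "inhibition": -1,
    "downregulation": -1,
}

EDGE_LIST_COLUMNS = ("source", "destination", "relation", "sign", "pathway_id")


@dataclass(frozen=True)
class RegEdge:
    """A signed directed regulation between two targets.

    ``sign`` is derived from ``relation`` (+1 for activation/expression,
    -1 for inhibition/repression), so the two can never disagree.
    """

    source: str
    destination: str
    relation: str
    pathway_id: str = ""

    def __post_init__(self) -> None:
        if self.relation not in RELATION_SIGNS:
            raise ValueError(
                f"unknown relation label {self.relation!r} on edge "
                f"{self.source!r} -> {self.destination!r}; expected one of "
                f"{sorted(RELATION_SIGNS)}"
            )

    @property
    def sign(self) -> int:
        return RELATION_SIGNS[self.relation]


@dataclass
class RegulatoryNetwork:
    """A signed directed graph of targets.

    At most two edges exist per ordered node pair (one per sign); duplicate
    (source, destination, sign) records are merged at construction with
    provenance tags concatenated. Use :func:`build_network` to construct.
    """

    nodes: set[str] = field(default_factory=set)
    edges: list[RegEdge] = field(default_factory=list)

    _successors: dict[str, list[tuple[str, int]]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def successors(self, node: str) -> list[tuple[str, int]]:
        """Outgoing (destination, sign) pairs of ``node``."""
        return self._successors.get(node, [])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_digraph(self) -> nx.DiGraph:
        """Unsigned directed view (one arc per ordered pair) for path queries."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.source, e.destination) for e in self.edges)
        return g


@dataclass
class DrugActionProfile:
    """A drug's immediate targets with their signed action labels."""

    drug_id: str
    actions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for target, action in self.actions.items():
            if action not in ACTION_SIGNS:
                raise ValueError(
                    f"unknown action label {action!r} for drug "
                    f"{self.drug_id!r} on target {target!r}"
                )

    def sign(self, target: str) -> int:
        return ACTION_SIGNS[self.actions[target]]

    def signed_targets(self) -> dict[str, int]:
        """Map target -> +/-1 derived from the action labels."""
        return {t: ACTION_SIGNS[a] for t, a in self.actions.items()}


@dataclass(frozen=True)
class CombinationRecord:
    """A labelled drug pair."""

    drug_a: str
    drug_b: str
    label: str
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.label not in ("synergism", "antagonism"):
            raise ValueError(f"label must be synergism or antagonism, got {self.label!r}")


def build_network(
    edges: Iterable[RegEdge], extra_nodes: Iterable[str] = ()
) -> RegulatoryNetwork:
    """Assemble a :class:`RegulatoryNetwork`, merging duplicate signed edges.

    Two records with the same (source, destination, sign) collapse into one
    edge whose pathway provenance tags are concatenated with ';'. The node
    set is the union of edge endpoints plus ``extra_nodes`` (for isolated
    nodes, e.g. from synthetic generators).
    """
    merged: dict[tuple[str, str, int], RegEdge] = {}
    n_in = 0
    n_merged = 0
    for edge in edges:
        n_in += 1
        key = (edge.source, edge.destination, edge.sign)
        prev = merged.get(key)
        if prev is None:
            merged[key] = edge
        else:
            n_merged += 1
            tags = [t for t in (prev.pathway_id, edge.pathway_id) if t]
            merged[key] = RegEdge(
                source=prev.source,
                destination=prev.destination,
                relation=prev.relation,
                pathway_id=";".join(tags),
            )
    kept = list(merged.values())
    nodes: set[str] = set(extra_nodes)
    successors: dict[str, list[tuple[str, int]]] = {}
    for e in kept:
        nodes.add(e.source)
        nodes.add(e.destination)
        successors.setdefault(e.source, []).append((e.destination, e.sign))
    logger.info("build_network: %d records in, %d merged, %d edges kept", n_in, n_merged, len(kept))
    return RegulatoryNetwork(nodes=nodes, edges=kept, _successors=successors)


def screen_key_targets(interactions: nx.Graph) -> set[str]:
    """Screen nodes with above-average degree, betweenness and closeness.

    Returns the nodes whose degree, betweenness and closeness centralities
    are each *strictly* greater than the respective mean over all nodes (so
    vertex-transitive graphs yield the empty set). Betweenness is
    unnormalized; closeness is computed within each node's connected
    component, with the mean taken over all nodes.
    """
    if interactions.number_of_nodes() == 0:
        logger.warning("screen_key_targets: empty graph, returning empty set")
        return set()
    degree = dict(interactions.degree())
    betweenness = nx.betweenness_centrality(interactions, normalized=False)
    closeness = nx.closeness_centrality(interactions, wf_improved=False)
    n = interactions.number_of_nodes()
    means = tuple(sum(c.values()) / n for c in (degree, betweenness, closeness))
    return {
        v
        for v in interactions.nodes
        if degree[v] > means[0] and betweenness[v] > means[1] and closeness[v] > means[2]
    }


def write_edge_list(network: RegulatoryNetwork, path) -> None:
    """Write the network's edges as TSV (source, destination, relation, sign, pathway_id)."""
    df = pd.DataFrame(
        [
            {
                "source": e.source,
                "destination": e.destination,
                "relation": e.relation,
                "sign": f"{e.sign:+d}",
                "pathway_id": e.pathway_id,
            }
            for e in network.edges
        ],
        columns=list(EDGE_LIST_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> RegulatoryNetwork:
    """Read a TSV edge list written by :func:`write_edge_list`."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    missing = set(EDGE_LIST_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"edge list missing required columns: {sorted(missing)}")
    edges = []
    for row in df.itertuples(index=False):
        edge = RegEdge(
            source=row.source,
            destination=row.destination,
            relation=row.relation,
            pathway_id=getattr(row, "pathway_id", ""),
        )
        if hasattr(row, "sign") and row.sign not in ("", None):
            declared = int(row.sign)
            if declared != edge.sign:
                raise ValueError(
                    f"sign column ({declared:+d}) contradicts relation "
                    f"{edge.relation!r} for edge {edge.source!r} -> {edge.destination!r}"
                )
        edges.append(edge)
    return build_network(edges)
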