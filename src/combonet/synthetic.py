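"""Synthetic signed networks and drug pairs with planted structure.

``generate_combination`` embeds a deterministic gadget inside a random
background: four target clusters (one positive and one negative per drug)
joined by short all-positive chains between the set pair that should end up
close, and by long chains (``cluster_separation`` hops) between the pairs
that should stay far but reachable. Background edges are confined to filler
nodes so they can never shortcut the planted geometry; filler nodes carry no
drug effect and therefore never enter any node set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from combonet.regnet_model import (
    CombinationRecord,
    DrugActionProfile,
    RegEdge,
    RegulatoryNetwork,
    build_network,
)

PLANTED_CHOICES = ("synergism", "antagonism", "none")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for synthetic network / drug-pair generation."""

    n_nodes: int = 60
    edge_prob: float = 0.02
    positive_edge_frac: float = 0.7
    targets_per_drug: int = 4
    planted: str = "none"
    cluster_separation: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.edge_prob < 1:
            raise ValueError(f"edge_prob must be in (0, 1), got {self.edge_prob}")
        if not 0 <= self.positive_edge_frac <= 1:
            raise ValueError(f"positive_edge_frac must be in [0, 1], got {self.positive_edge_frac}")
        if self.targets_per_drug < 1:
            raise ValueError("targets_per_drug must be >= 1")
        if self.planted not in PLANTED_CHOICES:
            raise ValueError(f"planted must be one of {PLANTED_CHOICES}, got {self.planted!r}")
        if self.cluster_separation < 3:
            raise ValueError("cluster_separation must be >= 3")


def _node_names(n: int, prefix: str = "T") -> list[str]:
    width = max(3, len(str(max(n - 1, 0))))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _random_edges(
    nodes: Sequence[str], edge_prob: float, positive_frac: float, rng: np.random.Generator
) -> list[RegEdge]:
    n = len(nodes)
    if n < 2:
        return []
    present = rng.random((n, n)) < edge_prob
    np.fill_diagonal(present, False)
    positive = rng.random((n, n)) < positive_frac
    edges = []
    for i, j in zip(*np.nonzero(present)):
        relation = "activation" if positive[i, j] else "inhibition"
        edges.append(RegEdge(source=nodes[i], destination=nodes[j], relation=relation))
    return edges


def generate_network(spec: SyntheticSpec) -> RegulatoryNetwork:
    """Directed G(n, p) with Bernoulli edge signs; reproducible from seed."""
    rng = np.random.default_rng(spec.seed)
    nodes = _node_names(spec.n_nodes)
    edges = _random_edges(nodes, spec.edge_prob, spec.positive_edge_frac, rng)
    return build_network(edges, extra_nodes=nodes)


def _chain(nodes: Sequence[str], relation: str = "activation") -> list[RegEdge]:
    return [
        RegEdge(source=a, destination=b, relation=relation)
        for a, b in zip(nodes, nodes[1:])
    ]


def generate_combination(
    spec: SyntheticSpec,
) -> tuple[RegulatoryNetwork, DrugActionProfile, DrugActionProfile, CombinationRecord]:
    """One drug pair on a network with planted synergy/antagonism geometry.

    For a synergism plant, the same-sign cluster pairs get short positive
    chains and the cross-sign pairs long ones; an antagonism plant swaps
    the roles. Long chains are routed so that they either start at a
    negatively-acted target (which never propagates) or exceed the
    propagation radius, keeping the planted set geometry analytic.
    """
    if spec.planted not in ("synergism", "antagonism"):
        raise ValueError("generate_combination requires planted synergism or antagonism")
    rng = np.random.default_rng(spec.seed)
    k = spec.targets_per_drug
    sep = spec.cluster_separation
    short_a = int(rng.integers(1, 3))  # chain lengths in hops
    short_b = int(rng.integers(1, 3))
    n_gadget = 4 * k + (short_a - 1) + (short_b - 1) + 2 * (sep - 1)
    if spec.n_nodes < n_gadget:
        raise ValueError(
            f"infeasible spec: {spec.n_nodes} nodes < {n_gadget} needed for the planted gadget"
        )
    names = _node_names(spec.n_nodes)
    order = rng.permutation(spec.n_nodes)
    pool = [names[i] for i in order]

    def take(m: int) -> list[str]:
        taken, pool[:] = pool[:m], pool[m:]
        return taken

    a_pos, a_neg, b_pos, b_neg = take(k), take(k), take(k), take(k)
    mid_a, mid_b = take(short_a - 1), take(short_b - 1)
    long_1, long_2 = take(sep - 1), take(sep - 1)
    filler = list(pool)

    edges: list[RegEdge] = []
    if spec.planted == "synergism":
        # close: A+ -> B+ and A- -> B-; far: B- -> A+ and A- -> B+
        edges += _chain([a_pos[0], *mid_a, b_pos[0]])
        edges += _chain([a_neg[0], *mid_b, b_neg[0]])
        edges += _chain([b_neg[0], *long_1, a_pos[0]])
        edges += _chain([a_neg[0], *long_2, b_pos[0]])
    else:
        # close: B- -> A+ and A- -> B+; far: A+ -> B+ and A- -> B-
        edges += _chain([b_neg[0], *mid_a, a_pos[0]])
        edges += _chain([a_neg[0], *mid_b, b_pos[0]])
        edges += _chain([a_pos[0], *long_1, b_pos[0]])
        edges += _chain([a_neg[0], *long_2, b_neg[0]])
    edges += _random_edges(filler, spec.edge_prob, spec.positive_edge_frac, rng)

    network = build_network(edges, extra_nodes=names)
    profile_a = DrugActionProfile(
        drug_id="A",
        actions={**{t: "activation" for t in a_pos}, **{t: "inhibition" for t in a_neg}},
    )
    profile_b = DrugActionProfile(
        drug_id="B",
        actions={**{t: "upregulation" for t in b_pos}, **{t: "downregulation" for t in b_neg}},
    )
    record = CombinationRecord(drug_a="A", drug_b="B", label=spec.planted)
    return network, profile_a, profile_b, record


def generate_benchmark(
    n_pairs: int, synergy_frac: float, spec: SyntheticSpec
) -> tuple[RegulatoryNetwork, dict[str, DrugActionProfile], list[CombinationRecord]]:
    """Labelled benchmark: disjoint planted instances merged into one network.

    Per-pair seeds derive hierarchically from ``spec.seed`` so any single
    instance can be regenerated in isolation. Node and drug identifiers are
    namespaced per pair, so instances live in disjoint components.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    if not 0 < synergy_frac < 1:
        raise ValueError("synergy_frac must be in (0, 1)")
    n_syn = round(n_pairs * synergy_frac)
    labels = ["synergism"] * n_syn + ["antagonism"] * (n_pairs - n_syn)
    child_seeds = [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(spec.seed).spawn(n_pairs)]

    all_edges: list[RegEdge] = []
    all_nodes: list[str] = []
    profiles: dict[str, DrugActionProfile] = {}
    records: list[CombinationRecord] = []
    for idx, (label, child_seed) in enumerate(zip(labels, child_seeds)):
        sub = replace(spec, planted=label, seed=child_seed)
        network, prof_a, prof_b, record = generate_combination(sub)
        prefix = f"P{idx:03d}:"
        all_nodes.extend(prefix + v for v in network.nodes)
        all_edges.extend(
            RegEdge(
                source=prefix + e.source,
                destination=prefix + e.destination,
                relation=e.relation,
                pathway_id=e.pathway_id,
            )
            for e in network.edges
        )
        for prof in (prof_a, prof_b):
            drug_id = prefix + prof.drug_id
            profiles[drug_id] = DrugActionProfile(
                drug_id=drug_id, actions={prefix + t: a for t, a in prof.actions.items()}
            )
        records.append(
            CombinationRecord(
                drug_a=prefix + record.drug_a, drug_b=prefix + record.drug_b, label=label
            )
        )
    return build_network(all_edges, extra_nodes=all_nodes), profiles, records
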