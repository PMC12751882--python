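"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results through different code paths:
exhaustive permutation enumeration for path effects, a literal double loop
over an all-pairs BFS matrix for set distances, and pairwise concordance
counting for AUC.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from combonet.regnet_model import (
    ACTION_SIGNS,
    DrugActionProfile,
    RegEdge,
    RegulatoryNetwork,
    build_network,
)


def brute_force_ia(
    network: RegulatoryNetwork,
    profile: DrugActionProfile,
    delta_pos: float,
    delta_neg: float,
    hop_max: int,
) -> dict[str, float]:
    """IA by exhaustive enumeration of all node permutations up to hop_max+1."""
    edge_signs: dict[tuple[str, str], list[int]] = {}
    for e in network.edges:
        edge_signs.setdefault((e.source, e.destination), []).append(e.sign)
    nodes = sorted(network.nodes)
    ia: dict[str, float] = {}
    for target, action in profile.actions.items():
        if target not in network.nodes:
            continue
        drug_sign = ACTION_SIGNS[action]
        ia[target] = ia.get(target, 0.0) + float(drug_sign)  # hop 0
        if drug_sign < 0:
            continue  # negatively-acted immediate targets do not propagate
        others = [v for v in nodes if v != target]
        for length in range(1, hop_max + 1):
            for tail in itertools.permutations(others, length):
                seq = (target,) + tail
                pairs = list(zip(seq, seq[1:]))
                if any(p not in edge_signs for p in pairs):
                    continue
                # non-terminal edges must be positive; terminal edge any sign
                sign_options = [edge_signs[p] for p in pairs]
                for combo in itertools.product(*sign_options):
                    if any(s < 0 for s in combo[:-1]):
                        continue
                    net_sign = drug_sign * int(np.prod(combo))
                    delta = delta_pos if net_sign > 0 else delta_neg
                    end = seq[-1]
                    ia[end] = ia.get(end, 0.0) + net_sign / delta**length
    return {v: w for v, w in ia.items()}


def brute_force_set_distance(
    network: RegulatoryNetwork, set_i: set[str], set_j: set[str]
) -> float | None:
    """Literal double-loop evaluation over an all-pairs BFS distance matrix."""
    if not set_i or not set_j:
        return None
    graph = network.to_digraph()
    matrix = dict(nx.all_pairs_shortest_path_length(graph))

    def one_direction(src: set[str], dst: set[str]) -> float | None:
        outer = []
        for i in sorted(src):
            inner = []
            for j in sorted(dst):
                if j in matrix.get(i, {}):
                    inner.append(matrix[i][j])
            if inner:
                outer.append(sum(inner) / len(inner))
        return sum(outer) / len(outer) if outer else None

    terms = [t for t in (one_direction(set_i, set_j), one_direction(set_j, set_i)) if t is not None]
    return sum(terms) / len(terms) if terms else None


def concordance_auc(scores, labels) -> float | None:
    """Mann-Whitney concordance probability with ties counted 0.5."""
    pos = [s for s, l in zip(scores, labels) if l == "synergism"]
    neg = [s for s, l in zip(scores, labels) if l == "antagonism"]
    if not pos or not neg:
        return None
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def random_network_and_profile(
    rng: np.random.Generator, n_max: int = 12
) -> tuple[RegulatoryNetwork, DrugActionProfile]:
    """Small random signed network (duplicate and two-sign edges allowed)
    with a random drug action profile."""
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    n_edges = int(rng.integers(0, 3 * n))
    relations = ["activation", "expression", "inhibition", "repression"]
    for _ in range(n_edges):
        src, dst = rng.choice(n, size=2, replace=False)
        edges.append(
            RegEdge(
                source=nodes[src],
                destination=nodes[dst],
                relation=relations[int(rng.integers(4))],
            )
        )
    network = build_network(edges, extra_nodes=nodes)
    n_targets = int(rng.integers(1, max(2, n // 2) + 1))
    chosen = rng.choice(n, size=n_targets, replace=False)
    actions = ["activation", "upregulation", "inhibition", "downregulation"]
    profile = DrugActionProfile(
        drug_id="drug",
        actions={nodes[t]: actions[int(rng.integers(4))] for t in chosen},
    )
    return network, profile
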