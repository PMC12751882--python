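"""Drug-effect propagation: per-node intensity of action with attenuation.

The intensity of action (IA) of a node is the sum, over every admissible
drug-action path ending there, of ``net_sign / delta**hop`` where ``delta``
is the attenuation coefficient matching the path's net sign. A path is
admissible when it starts at an immediate target, is simple, is at most
``hop_max`` edges long, and respects blocking: a negative edge terminates
its path, and a negatively-acted immediate target does not propagate at all.
Under these rules every non-terminal edge on a path is positive, so the net
sign is the drug sign times the terminal edge sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import pandas as pd

from combonet.regnet_model import DrugActionProfile, RegulatoryNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AttenuationParams:
    """Per-hop damping coefficients (>= 1) and the propagation radius."""

    delta_pos: float = 1.5
    delta_neg: float = 1.1
    hop_max: int = 2

    def __post_init__(self) -> None:
        if self.delta_pos < 1 or self.delta_neg < 1:
            raise ValueError(
                f"attenuation coefficients must be >= 1, got "
                f"delta_pos={self.delta_pos}, delta_neg={self.delta_neg}"
            )
        if self.hop_max < 0:
            raise ValueError(f"hop_max must be >= 0, got {self.hop_max}")


@dataclass(frozen=True)
class ActionPath:
    """A single admissible drug-action path.

    ``nodes`` runs from an immediate target to the path's endpoint;
    ``edge_signs`` has one +/-1 per hop (all non-terminal signs are +1 by
    the blocking rule); ``drug_sign`` is the sign of the drug's action on
    the starting node.
    """

    nodes: tuple[str, ...]
    edge_signs: tuple[int, ...]
    drug_sign: int

    @property
    def hop(self) -> int:
        return len(self.nodes) - 1

    @property
    def net_sign(self) -> int:
        sign = self.drug_sign
        for s in self.edge_signs:
            sign *= s
        return sign

    @property
    def end(self) -> str:
        return self.nodes[-1]


@dataclass
class NodeEffectProfile:
    """Per-node IA values with the derived positive/negative node sets.

    Nodes with IA exactly 0 belong to neither set.
    """

    ia: dict[str, float] = field(default_factory=dict)
    positive_set: set[str] = field(default_factory=set)
    negative_set: set[str] = field(default_factory=set)

    @classmethod
    def from_ia(cls, ia: Mapping[str, float]) -> "NodeEffectProfile":
        pos, neg = partition_nodes(ia)
        return cls(ia=dict(ia), positive_set=pos, negative_set=neg)


def enumerate_action_paths(
    network: RegulatoryNetwork, profile: DrugActionProfile, hop_max: int = 2
) -> Iterator[ActionPath]:
    """Yield every admissible simple path of 0..hop_max hops for a drug.

    Profile targets absent from the network are skipped with a warning.
    Paths are truncated by blocking: a path whose latest edge is negative is
    terminal, and a negatively-acted immediate target yields only its
    zero-hop path.
    """
    for target, drug_sign in profile.signed_targets().items():
        if target not in network.nodes:
            logger.warning(
                "drug %r target %r absent from network; skipped", profile.drug_id, target
            )
            continue
        yield ActionPath(nodes=(target,), edge_signs=(), drug_sign=drug_sign)
        if drug_sign < 0:
            continue  # drug-level block: inhibited targets do not forward
        stack: list[tuple[tuple[str, ...], tuple[int, ...]]] = [((target,), ())]
        while stack:
            nodes, signs = stack.pop()
            if len(nodes) - 1 >= hop_max:
                continue
            for dest, sign in network.successors(nodes[-1]):
                if dest in nodes:
                    continue  # simple paths only
                path = ActionPath(nodes=nodes + (dest,), edge_signs=signs + (sign,), drug_sign=drug_sign)
                yield path
                if sign > 0:  # negative edge blocks further propagation
                    stack.append((path.nodes, path.edge_signs))


def compute_ia(
    network: RegulatoryNetwork,
    profile: DrugActionProfile,
    params: AttenuationParams | None = None,
) -> NodeEffectProfile:
    """Sum attenuated path contributions into per-node IA values.

    Each path ending at ``v`` contributes ``net_sign / delta**hop`` with
    ``delta = delta_pos`` for positive-net-sign paths and ``delta_neg`` for
    negative ones; the zero-hop path contributes exactly +/-1.
    """
    if params is None:
        params = AttenuationParams()
    if not profile.actions:
        logger.warning("drug %r has an empty action profile", profile.drug_id)
        return NodeEffectProfile()
    ia: dict[str, float] = {}
    for path in enumerate_action_paths(network, profile, params.hop_max):
        sign = path.net_sign
        delta = params.delta_pos if sign > 0 else params.delta_neg
        ia[path.end] = ia.get(path.end, 0.0) + sign / delta**path.hop
    return NodeEffectProfile.from_ia(ia)


def partition_nodes(profile: NodeEffectProfile | Mapping[str, float]) -> tuple[set[str], set[str]]:
    """Split nodes into (IA > 0, IA < 0) sets; IA = 0 nodes are excluded.

    The comparison with 0 is exact: contributions are sums of exact
    reciprocals and a tolerance would silently change set membership.
    """
    ia = profile.ia if isinstance(profile, NodeEffectProfile) else profile
    positive = {v for v, w in ia.items() if w > 0}
    negative = {v for v, w in ia.items() if w < 0}
    return positive, negative


def write_effect_profile(profile: NodeEffectProfile, path) -> None:
    """Dump per-node IA values as TSV (node, ia, set in {pos, neg, zero})."""
    rows = [
        {
            "node": v,
            "ia": repr(w),
            "set": "pos" if v in profile.positive_set else "neg" if v in profile.negative_set else "zero",
        }
        for v, w in sorted(profile.ia.items())
    ]
    pd.DataFrame(rows, columns=["node", "ia", "set"]).to_csv(path, sep="\t", index=False)
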