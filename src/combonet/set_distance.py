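"""Relative node-set distances and the synergy/antagonism call.

The distance between two node sets averages, per source node, the directed
hop-count shortest-path distances to the reachable members of the other set,
then averages over source nodes with at least one reachable member, and
finally averages the two directions (or keeps the single defined one).
A pair of sets with no reachability in either direction has an UNDEFINED
distance, represented as ``None`` and serialized as ``NA``.

The call for a drug pair compares the same-sign set distances against the
minimum cross-sign set distance: both relative distances negative means
synergism, either positive means antagonism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

from combonet.propagation import AttenuationParams, compute_ia
from combonet.regnet_model import DrugActionProfile, RegulatoryNetwork

logger = logging.getLogger(__name__)

#: sentinel for an undefined distance / relative distance / score
UNDEFINED = None

SYNERGISM = "synergism"
ANTAGONISM = "antagonism"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class SetDistances:
    """The four set distances for a drug pair (None where undefined).

    ``d_pp``/``d_mm`` are the same-sign (forward-regulated) distances
    d(|I+,J+|) and d(|I-,J-|); ``d_pm``/``d_mp`` the cross-sign
    (reverse-regulated) ones d(|I+,J-|) and d(|I-,J+|).
    """

    d_pp: float | None
    d_mm: float | None
    d_pm: float | None
    d_mp: float | None


@dataclass(frozen=True)
class CombinationAssessment:
    """Scored verdict for one drug pair."""

    drug_a: str
    drug_b: str
    distances: SetDistances
    d_plus: float | None
    d_minus: float | None
    call: str
    score: float | None


def _directed_term(dist: dict[str, dict[str, int]], sources: set[str], targets: set[str]) -> float | None:
    """Mean over sources (with >=1 reachable target) of their mean distance
    to the reachable targets; None when no source reaches any target."""
    per_source = []
    for i in sources:
        row = dist.get(i, {})
        reach = [row[j] for j in targets if j in row]
        if reach:
            per_source.append(sum(reach) / len(reach))
    if not per_source:
        return None
    return sum(per_source) / len(per_source)


def set_distance(
    network: RegulatoryNetwork, set_i: Iterable[str], set_j: Iterable[str]
) -> float | None:
    """Relative network distance between two node sets (None if undefined).

    Distances are hop counts on the full directed network, ignoring edge
    signs; a node in both sets contributes d(i,i)=0. If only one direction
    has any reachability the result is that direction's term alone.
    """
    set_i, set_j = set(set_i), set(set_j)
    if not set_i <= network.nodes or not set_j <= network.nodes:
        stray = (set_i | set_j) - network.nodes
        raise ValueError(f"node sets contain nodes absent from the network: {sorted(stray)}")
    if not set_i or not set_j:
        logger.warning("set_distance: empty node set, distance undefined")
        return UNDEFINED
    graph = network.to_digraph()
    dist = {
        v: nx.single_source_shortest_path_length(graph, v) for v in set_i | set_j
    }
    forward = _directed_term(dist, set_i, set_j)
    backward = _directed_term(dist, set_j, set_i)
    defined = [t for t in (forward, backward) if t is not None]
    if not defined:
        return UNDEFINED
    return sum(defined) / len(defined)


def relative_distances(d: SetDistances) -> tuple[float | None, float | None]:
    """Same-sign distances minus the minimum defined cross-sign distance.

    Returns (d_plus, d_minus); an output is None when the cross-sign
    minimum has no defined member or its same-sign distance is undefined.
    """
    cross = [x for x in (d.d_pm, d.d_mp) if x is not None]
    if not cross:
        return UNDEFINED, UNDEFINED
    m = min(cross)
    d_plus = d.d_pp - m if d.d_pp is not None else UNDEFINED
    d_minus = d.d_mm - m if d.d_mm is not None else UNDEFINED
    return d_plus, d_minus


def classify(d_plus: float | None, d_minus: float | None) -> str:
    """Call synergism (both negative), antagonism (either positive), or
    indeterminate (any undefined, or neither rule fires)."""
    if d_plus is None or d_minus is None:
        return INDETERMINATE
    if d_plus < 0 and d_minus < 0:
        return SYNERGISM
    if d_plus > 0 or d_minus > 0:
        return ANTAGONISM
    return INDETERMINATE


def synergy_score(d_plus: float | None, d_minus: float | None) -> float | None:
    """Continuous ranking score: -max(d_plus, d_minus); larger = more
    synergistic. None when either input is undefined (pair excluded from
    ranking-based evaluation)."""
    if d_plus is None or d_minus is None:
        logger.warning("synergy_score: undefined relative distance, score undefined")
        return UNDEFINED
    return -max(d_plus, d_minus)


def assess_pair(
    network: RegulatoryNetwork,
    profile_a: DrugActionProfile,
    profile_b: DrugActionProfile,
    params: AttenuationParams | None = None,
) -> CombinationAssessment:
    """Full pipeline for one drug pair: IA -> node sets -> distances -> call."""
    if params is None:
        params = AttenuationParams()
    effects_a = compute_ia(network, profile_a, params)
    effects_b = compute_ia(network, profile_b, params)
    for drug, eff in ((profile_a.drug_id, effects_a), (profile_b.drug_id, effects_b)):
        if not eff.positive_set and not eff.negative_set:
            logger.warning("drug %r has no nonzero-effect nodes; pair indeterminate", drug)
            distances = SetDistances(None, None, None, None)
            return CombinationAssessment(
                drug_a=profile_a.drug_id,
                drug_b=profile_b.drug_id,
                distances=distances,
                d_plus=UNDEFINED,
                d_minus=UNDEFINED,
                call=INDETERMINATE,
                score=UNDEFINED,
            )

    def dist(i: set[str], j: set[str]) -> float | None:
        if not i or not j:
            return UNDEFINED
        return set_distance(network, i, j)

    distances = SetDistances(
        d_pp=dist(effects_a.positive_set, effects_b.positive_set),
        d_mm=dist(effects_a.negative_set, effects_b.negative_set),
        d_pm=dist(effects_a.positive_set, effects_b.negative_set),
        d_mp=dist(effects_a.negative_set, effects_b.positive_set),
    )
    d_plus, d_minus = relative_distances(distances)
    call = classify(d_plus, d_minus)
    score = synergy_score(d_plus, d_minus)
    return CombinationAssessment(
        drug_a=profile_a.drug_id,
        drug_b=profile_b.drug_id,
        distances=distances,
        d_plus=d_plus,
        d_minus=d_minus,
        call=call,
        score=score,
    )


def _na(x: float | None) -> str:
    return "NA" if x is None else repr(float(x))


def write_assessments(assessments: Iterable[CombinationAssessment], path) -> None:
    """Dump assessments as TSV; undefined values serialize as NA."""
    rows = [
        {
            "drug_a": a.drug_a,
            "drug_b": a.drug_b,
            "d_pp": _na(a.distances.d_pp),
            "d_mm": _na(a.distances.d_mm),
            "d_pm": _na(a.distances.d_pm),
            "d_mp": _na(a.distances.d_mp),
            "d_plus": _na(a.d_plus),
            "d_minus": _na(a.d_minus),
            "call": a.call,
            "score": _na(a.score),
        }
        for a in assessments
    ]
    columns = ["drug_a", "drug_b", "d_pp", "d_mm", "d_pm", "d_mp", "d_plus", "d_minus", "call", "score"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
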