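"""Readers/writers: KGML pathway XML, drug-target tables, pair-label tables.

KGML parsing keeps only PPrel/GErel relations whose subtype list contains a
signed regulation (activation, inhibition, expression, repression). Entry
``name`` fields holding several space-separated identifiers expand
combinatorially, group entries expand to their component entries, and
non-gene entries (maps, compounds, ...) are dropped with counts.
"""

from __future__ import annotations

import collections
import io
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from combonet.regnet_model import (
    ACTION_SIGNS,
    RELATION_SIGNS,
    CombinationRecord,
    DrugActionProfile,
    RegEdge,
)

logger = logging.getLogger(__name__)

SIGNED_SUBTYPES = tuple(RELATION_SIGNS)  # activation, expression, inhibition, repression
RELATION_TYPES = ("PPrel", "GErel")
COMBINATION_LABELS = ("synergism", "antagonism")


@dataclass(frozen=True)
class KgmlRelationRecord:
    """A raw KGML relation element, before expansion to edges."""

    entry1: str
    entry2: str
    relation_type: str
    subtypes: tuple[str, ...] = ()


@dataclass
class ParseReport:
    """Edges extracted from one KGML document plus skip counts by reason."""

    edges: list[RegEdge] = field(default_factory=list)
    skipped: collections.Counter = field(default_factory=collections.Counter)


def _entry_names(root: ET.Element) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Map entry id -> gene names; group entries expand to component genes."""
    gene_names: dict[str, list[str]] = {}
    components: dict[str, list[str]] = {}
    for entry in root.iter("entry"):
        eid = entry.get("id", "")
        etype = entry.get("type", "")
        if etype == "gene":
            gene_names[eid] = entry.get("name", "").split()
        elif etype == "group":
            components[eid] = [c.get("id", "") for c in entry.iter("component")]
    # resolve groups to the union of their gene components
    group_names: dict[str, list[str]] = {}
    for gid, comp_ids in components.items():
        names: list[str] = []
        for cid in comp_ids:
            names.extend(gene_names.get(cid, []))
        group_names[gid] = names
    return gene_names, group_names


def parse_kgml(document: str | bytes | io.IOBase, pathway_id: str | None = None) -> ParseReport:
    """Extract signed regulation edges from a KGML pathway document.

    Emits one directed edge entry1 -> entry2 per (name-of-entry1,
    name-of-entry2) pair for every PPrel/GErel relation carrying at least
    one signed subtype; a relation carrying both a positive and a negative
    subtype emits one edge per sign. Everything else is counted in
    ``skipped``. ``pathway_id`` defaults to the document's ``name`` attribute.
    """
    if isinstance(document, (str, bytes)):
        root = ET.fromstring(document)
    else:
        root = ET.parse(document).getroot()
    if root.tag != "pathway":
        raise ValueError(f"not a KGML document: root element is <{root.tag}>")
    if pathway_id is None:
        pathway_id = root.get("name", "")

    gene_names, group_names = _entry_names(root)
    report = ParseReport()

    def names_of(eid: str) -> list[str] | None:
        if eid in gene_names:
            return gene_names[eid]
        if eid in group_names:
            return group_names[eid]
        return None

    for rel in root.iter("relation"):
        rtype = rel.get("type", "")
        if rtype not in RELATION_TYPES:
            report.skipped[f"relation_type:{rtype or 'missing'}"] += 1
            continue
        subtype_names = [s.get("name", "") for s in rel.iter("subtype")]
        # dedupe signed labels while preserving KGML subtype order
        signed = list(dict.fromkeys(s for s in subtype_names if s in SIGNED_SUBTYPES))
        if not signed:
            report.skipped["unsigned_subtype"] += 1
            continue
        src_names = names_of(rel.get("entry1", ""))
        dst_names = names_of(rel.get("entry2", ""))
        if src_names is None or dst_names is None:
            report.skipped["non_gene_or_unknown_entry"] += 1
            continue
        if not src_names or not dst_names:
            report.skipped["empty_entry_name"] += 1
            continue
        # one signed relation per distinct sign (activation + inhibition -> both)
        seen_signs: set[int] = set()
        for label in signed:
            if RELATION_SIGNS[label] in seen_signs:
                continue
            seen_signs.add(RELATION_SIGNS[label])
            for src in src_names:
                for dst in dst_names:
                    report.edges.append(
                        RegEdge(source=src, destination=dst, relation=label, pathway_id=pathway_id)
                    )
    if report.skipped:
        logger.info("parse_kgml(%s): skipped %s", pathway_id, dict(report.skipped))
    return report


def _read_table(path_or_buf, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path_or_buf, sep="\t", comment="#", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"table missing required columns: {sorted(missing)}")
    return df


def read_drug_targets(path_or_buf) -> list[DrugActionProfile]:
    """Read a TSV with columns drug_id, target, action into action profiles.

    Duplicate (drug, target) rows with identical action are deduped;
    conflicting actions for the same (drug, target) raise, never silently
    override.
    """
    df = _read_table(path_or_buf, ("drug_id", "target", "action"))
    actions: dict[str, dict[str, str]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        action = row.action.strip().lower()
        if action not in ACTION_SIGNS:
            raise ValueError(
                f"row {idx}: unknown action label {row.action!r} "
                f"(drug {row.drug_id!r}, target {row.target!r})"
            )
        per_drug = actions.setdefault(row.drug_id, {})
        prev = per_drug.get(row.target)
        if prev is not None and prev != action:
            raise ValueError(
                f"row {idx}: conflicting actions for drug {row.drug_id!r} on "
                f"target {row.target!r}: {prev!r} vs {action!r}"
            )
        per_drug[row.target] = action
    return [DrugActionProfile(drug_id=d, actions=a) for d, a in actions.items()]


def write_drug_targets(profiles: Iterable[DrugActionProfile], path) -> None:
    rows = [
        {"drug_id": p.drug_id, "target": t, "action": a}
        for p in profiles
        for t, a in p.actions.items()
    ]
    pd.DataFrame(rows, columns=["drug_id", "target", "action"]).to_csv(path, sep="\t", index=False)


def read_combinations(path_or_buf) -> list[CombinationRecord]:
    """Read a TSV with columns drug_a, drug_b, label (optional condition).

    Labels are normalized case-insensitively to synergism/antagonism; pair
    order is preserved as given. A self-pair is accepted with a warning.
    """
    df = _read_table(path_or_buf, ("drug_a", "drug_b", "label"))
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        label = row.label.strip().lower()
        if label not in COMBINATION_LABELS:
            raise ValueError(
                f"row {idx}: unknown combination label {row.label!r} "
                f"(pair {row.drug_a!r}, {row.drug_b!r})"
            )
        if row.drug_a == row.drug_b:
            logger.warning("row %d: self-pair (%r, %r)", idx, row.drug_a, row.drug_b)
        condition = getattr(row, "condition", "") or None
        records.append(
            CombinationRecord(drug_a=row.drug_a, drug_b=row.drug_b, label=label, condition=condition)
        )
    return records


def write_combinations(records: Iterable[CombinationRecord], path) -> None:
    rows = [
        {"drug_a": r.drug_a, "drug_b": r.drug_b, "label": r.label, "condition": r.condition or ""}
        for r in records
    ]
    pd.DataFrame(rows, columns=["drug_a", "drug_b", "label", "condition"]).to_csv(
        path, sep="\t", index=False
    )
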