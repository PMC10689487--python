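"""Roll concept calls up to deliveries and apply the PPH definition.

A delivery is represented by the patient's notes whose dates chain within a
configurable gap. Estimated-blood-loss segments are pooled across the group's
notes (same-value de-duplication applies across the whole group, since a
second note for one delivery typically restates the same loss), the delivery
mode is cesarean iff the cesarean-delivery concept fires on any note, and the
PPH flag uses the historical strict rule: total EBL > 500 mL for a vaginal
delivery or > 1000 mL for a cesarean delivery. The post-2018 definition
(> 1000 mL regardless of mode) ships as a preset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import ebl as _ebl
from .corpus_io import NoteRecord
from .extraction import ConceptCall

__all__ = [
    "PhenotypeRule",
    "HISTORICAL_RULE",
    "ACOG2017_RULE",
    "DeliveryAssessment",
    "group_notes",
    "infer_mode",
    "classify_pph",
    "assess_deliveries",
    "prevalence_table",
]

CESAREAN_CONCEPT = "cesarean_delivery"
EBL_CONCEPT = "estimated_blood_loss"


@dataclass(frozen=True)
class PhenotypeRule:
    """Strict-greater EBL thresholds per delivery mode, in mL."""

    vaginal_threshold_ml: float = 500.0
    cesarean_threshold_ml: float = 1000.0

    def __post_init__(self) -> None:
        if self.cesarean_threshold_ml < self.vaginal_threshold_ml:
            raise ValueError("cesarean threshold must be >= vaginal threshold")


HISTORICAL_RULE = PhenotypeRule(500.0, 1000.0)
#: Current definition: at least 1000 mL regardless of delivery mode.
ACOG2017_RULE = PhenotypeRule(1000.0, 1000.0)

RULE_PRESETS = {"historical": HISTORICAL_RULE, "acog2017": ACOG2017_RULE}


@dataclass(frozen=True)
class DeliveryAssessment:
    delivery_id: str
    patient_id: str
    note_ids: tuple[str, ...]
    note_dates: tuple[date, ...]
    ebl_values: tuple[float, ...]
    total_ebl_ml: float
    mode: str  # cesarean | vaginal
    pph: bool
    concept_flags: Mapping[str, bool] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "delivery_id": self.delivery_id,
            "patient_id": self.patient_id,
            "note_ids": list(self.note_ids),
            "note_dates": [d.isoformat() for d in self.note_dates],
            "ebl_values": list(self.ebl_values),
            "total_ebl_ml": self.total_ebl_ml,
            "mode": self.mode,
            "pph": self.pph,
            "concept_flags": dict(self.concept_flags),
        }


def group_notes(notes: Sequence[NoteRecord], max_gap_days: int = 7) -> list[list[NoteRecord]]:
    """Chain a patient's notes into delivery groups.

    Notes are sorted by (patient, date, note_id); consecutive notes of one
    patient with a date gap of at most ``max_gap_days`` share a group. The
    result is independent of input order.
    """
    ordered = sorted(notes, key=lambda n: (n.patient_id, n.note_date, n.note_id))
    groups: list[list[NoteRecord]] = []
    for n in ordered:
        if (
            groups
            and groups[-1][-1].patient_id == n.patient_id
            and (n.note_date - groups[-1][-1].note_date).days <= max_gap_days
        ):
            groups[-1].append(n)
        else:
            groups.append([n])
    return groups


def infer_mode(calls: Sequence[ConceptCall], note_ids: Iterable[str] | None = None) -> str:
    """Cesarean iff the cesarean-delivery call is positive on any note of the
    group; vaginal otherwise. Every group note must carry the call."""
    ces = [c for c in calls if c.concept_id == CESAREAN_CONCEPT]
    have = {c.note_id for c in ces}
    required = set(note_ids) if note_ids is not None else have
    missing = required - have
    if missing or not ces:
        raise ValueError(f"missing {CESAREAN_CONCEPT} call for notes: {sorted(missing) or 'all'}")
    return "cesarean" if any(c.label for c in ces if c.note_id in required) else "vaginal"


def classify_pph(total_ebl_ml: float, mode: str, rule: PhenotypeRule = HISTORICAL_RULE) -> bool:
    if total_ebl_ml < 0:
        raise ValueError("total EBL must be non-negative")
    if mode == "cesarean":
        return total_ebl_ml > rule.cesarean_threshold_ml
    if mode == "vaginal":
        return total_ebl_ml > rule.vaginal_threshold_ml
    raise ValueError(f"unknown delivery mode {mode!r}")


def assess_deliveries(
    notes: Sequence[NoteRecord],
    calls: Sequence[ConceptCall],
    rule: PhenotypeRule = HISTORICAL_RULE,
    max_gap_days: int = 7,
    groups: Sequence[Sequence[NoteRecord]] | None = None,
) -> list[DeliveryAssessment]:
    """Per delivery group: pool EBL segments, infer mode, classify PPH, and
    carry delivery-level concept flags as evidence.

    A caller-supplied ``groups`` partition (e.g. from a delivery_id column)
    bypasses date-gap grouping.
    """
    index: dict[tuple[str, str], ConceptCall] = {(c.note_id, c.concept_id): c for c in calls}
    concept_ids = sorted({c.concept_id for c in calls})
    if groups is None:
        groups = group_notes(notes, max_gap_days)

    assessments = []
    for group in groups:
        note_ids = tuple(n.note_id for n in group)
        segments: set[str] = set()
        for nid in note_ids:
            call = index.get((nid, EBL_CONCEPT))
            if call is None:
                raise ValueError(f"missing {EBL_CONCEPT} call for note {nid}")
            segments |= set(call.segments or ())
        summary = _ebl.summarize(_ebl.parse_mentions(segments))
        group_calls = [index[(nid, cid)] for nid in note_ids for cid in concept_ids if (nid, cid) in index]
        mode = infer_mode(group_calls, note_ids)
        flags = {
            cid: any(
                bool(index[(nid, cid)].label)
                for nid in note_ids
                if (nid, cid) in index and index[(nid, cid)].label is not None
            )
            for cid in concept_ids
            if cid != EBL_CONCEPT
        }
        first = group[0]
        assessments.append(
            DeliveryAssessment(
                delivery_id=f"{first.patient_id}:{first.note_date.isoformat()}",
                patient_id=first.patient_id,
                note_ids=note_ids,
                note_dates=tuple(n.note_date for n in group),
                ebl_values=summary.values_ml,
                total_ebl_ml=summary.total_ml,
                mode=mode,
                pph=classify_pph(summary.total_ml, mode, rule),
                concept_flags=flags,
            )
        )
    return assessments


def prevalence_table(
    assessments: Sequence[DeliveryAssessment],
    concept_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Count and percentage of PPH-positive deliveries with each concept
    positive (denominator = PPH-positive deliveries)."""
    pph = [a for a in assessments if a.pph]
    if not pph:
        warnings.warn("no PPH-positive deliveries; prevalence table is empty")
        return pd.DataFrame(columns=["count", "percentage"])
    if concept_ids is None:
        concept_ids = sorted({cid for a in pph for cid in a.concept_flags})
    rows = []
    for cid in concept_ids:
        count = sum(bool(a.concept_flags.get(cid)) for a in pph)
        rows.append({"concept_id": cid, "count": count, "percentage": 100.0 * count / len(pph)})
    df = pd.DataFrame(rows).set_index("concept_id")
    return df.sort_values("count", ascending=False)
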