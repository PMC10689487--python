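"""Synthetic obstetric discharge summaries with known ground truth.

The generator emulates the structural properties of delivery discharge
summaries that matter to this pipeline — concept mentions drawn from phrase
banks, estimated-blood-loss values written in heterogeneous formats (mL, cc,
liters, bare numbers, concatenated shorthand like ``500ccf/b``), polysemy
distractors (rupture of membranes, misoprostol for cervical ripening),
optional misspelling/abbreviation corruption, and multi-note deliveries that
restate the same blood loss — not clinical fluency.

With corruption off, every planted concept phrase is matched by the shipped
pattern sets and every planted EBL value is recoverable, which makes the
generator a valid oracle for end-to-end tests: the pattern backend must
achieve sensitivity = PPV = 1 on a clean corpus.

Truth is self-consistent by construction: delivery-level PPH flags are
computed by the phenotyping rule from the planted totals, and subtype flags
by the NLP subtyping rule from the planted concept flags.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import GoldAnnotation, IcdRecord, NoteRecord
from .phenotyping import HISTORICAL_RULE, PhenotypeRule, classify_pph
from .registry import (
    CONCEPT_PHRASES,
    DISTRACTOR_PHRASES,
    VAGINAL_PHRASES,
    builtin_registry,
)
from .subtyping import SUBTYPES, SUBTYPE_CONCEPTS, nlp_subtype

__all__ = ["SynthConfig", "NoteTruth", "DeliveryTruth", "SynthTruth", "generate", "corrupt", "truth_report", "generate_icd"]

#: Per-note prevalence of each binary concept, matching the concept mix of an
#: annotated PPH-enriched note sample (positives per 1175 notes).
DEFAULT_PREVALENCE: dict[str, float] = {
    "laceration": 0.358,
    "bakri_balloon": 0.039,
    "methylergonovine": 0.089,
    "placenta_previa": 0.145,
    "fresh_frozen_plasma": 0.067,
    "carboprost": 0.042,
    "misoprostol_uterotonic": 0.095,
    "hysterectomy": 0.047,
    "oleary_sutures": 0.010,
    "uterine_atony": 0.091,
    "retained_products": 0.087,
    "pph_mention": 0.308,
    "prbc": 0.140,
    "abruption": 0.040,
    "coagulation_disorders": 0.037,
    "cryoprecipitate": 0.025,
    "dilation_curettage": 0.104,
    "platelets": 0.025,
    "accreta_spectrum": 0.038,
    "manual_extraction_placenta": 0.094,
    "pph_surgical": 0.023,
    "uterine_rupture": 0.004,
}

EBL_FORMATS = ("ml", "cc", "liters", "bare", "concat")
DEFAULT_FORMAT_WEIGHTS: dict[str, float] = {"ml": 0.35, "cc": 0.30, "liters": 0.10, "bare": 0.15, "concat": 0.10}

HOSPITALS = ("BWH", "MGH", "NSM", "NWH")

#: Phrase-level abbreviation map used by :func:`corrupt`.
ABBREVIATIONS: dict[str, str] = {
    "dilation and curettage": "d&c",
    "postpartum hemorrhage": "pph",
    "packed red blood cells": "prbc",
    "fresh frozen plasma": "ffp",
    "retained products of conception": "retained poc",
    "estimated blood loss": "ebl",
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters. ``n_notes`` counts deliveries (primary notes); a
    ``multi_note_fraction`` of deliveries emit a second note 0-3 days later
    restating the same concepts and blood loss, so the total note count can
    exceed ``n_notes``."""

    n_notes: int = 500
    seed: int = 0
    concept_prevalence: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    cesarean_rate: float = 0.32
    pph_rate: float = 0.10
    p_no_ebl: float = 0.15
    ebl_format_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FORMAT_WEIGHTS))
    misspell_rate: float = 0.0
    abbrev_rate: float = 0.0
    distractor_rate: float = 0.10
    multi_note_fraction: float = 0.15
    max_note_gap_days: int = 3
    start_date: date = date(1998, 1, 1)
    end_date: date = date(2015, 4, 30)
    rule: PhenotypeRule = HISTORICAL_RULE

    def __post_init__(self) -> None:
        if self.n_notes <= 0:
            raise ValueError("n_notes must be positive")
        for name in ("cesarean_rate", "pph_rate", "p_no_ebl", "misspell_rate",
                     "abbrev_rate", "distractor_rate", "multi_note_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class NoteTruth:
    concept_flags: Mapping[str, bool]  # all 23 binary concepts
    ebl_values: tuple[float, ...]  # normalized mL
    mode: str


@dataclass(frozen=True)
class DeliveryTruth:
    delivery_id: str
    patient_id: str
    note_ids: tuple[str, ...]
    mode: str
    total_ebl_ml: float
    pph: bool
    subtypes: Mapping[str, bool]
    concept_flags: Mapping[str, bool]


@dataclass(frozen=True)
class SynthTruth:
    notes: Mapping[str, NoteTruth]
    deliveries: tuple[DeliveryTruth, ...]


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

_WORD_RE = re.compile(r"[A-Za-z]{4,}")


def corrupt(
    text: str,
    misspell_rate: float = 0.0,
    abbrev_rate: float = 0.0,
    seed: int = 0,
    preserve_numbers: bool = True,
) -> str:
    """Word-level perturbation: adjacent-character swaps / character drops at
    ``misspell_rate``, abbreviation substitution at ``abbrev_rate``.

    Deterministic given the seed. With ``preserve_numbers`` (default) numeric
    tokens are never touched, so planted blood-loss values survive.
    """
    if not (0 <= misspell_rate < 1 and 0 <= abbrev_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)

    if abbrev_rate > 0:
        for phrase, abbrev in ABBREVIATIONS.items():
            out = []
            cursor = 0
            for m in re.finditer(re.escape(phrase), text, re.IGNORECASE):
                out.append(text[cursor : m.start()])
                out.append(abbrev if rng.random() < abbrev_rate else m.group())
                cursor = m.end()
            out.append(text[cursor:])
            text = "".join(out)

    if misspell_rate > 0:
        def _mangle(m: re.Match) -> str:
            word = m.group()
            if rng.random() >= misspell_rate:
                return word
            i = int(rng.integers(0, len(word) - 1))
            if rng.random() < 0.5:  # swap adjacent characters
                return word[:i] + word[i + 1] + word[i] + word[i + 2 :]
            return word[:i] + word[i + 1 :]  # drop one character

        # numeric tokens contain no [A-Za-z]{4,} runs, so the word regex
        # already leaves numbers intact; preserve_numbers additionally skips
        # words adjacent to digits (unit tokens like "mL" are < 4 chars).
        if preserve_numbers:
            text = _WORD_RE.sub(lambda m: m.group() if _near_digit(text, m) else _mangle(m), text)
        else:
            text = _WORD_RE.sub(_mangle, text)
    return text


def _near_digit(text: str, m: re.Match) -> bool:
    before = text[max(0, m.start() - 2) : m.start()]
    after = text[m.end() : m.end() + 2]
    return any(ch.isdigit() for ch in before + after)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _format_ebl(value: float, fmt: str) -> str:
    """Render one EBL sentence in the requested surface format."""
    v = int(value) if float(value).is_integer() else value
    if fmt == "liters" and value % 100 == 0:
        liters = value / 1000.0
        ltext = f"{liters:g}"
        return f"Estimated blood loss {ltext} L."
    if fmt == "liters":
        fmt = "ml"
    if fmt == "ml":
        return f"Estimated blood loss was {v} mL."
    if fmt == "cc":
        return f"EBL: {v}cc."
    if fmt == "bare":
        return f"EBL {v}."
    if fmt == "concat":
        return f"EBL {v}ccf/b stable hematocrit."
    raise ValueError(f"unknown EBL format {fmt!r}")


def _note_text(
    rng: np.random.Generator,
    mode: str,
    flags: Mapping[str, bool],
    ebl_value: float | None,
    ebl_fmt: str | None,
    distractor: str | None,
    admit: date,
    addendum: bool = False,
) -> str:
    mode_phrase = (
        CONCEPT_PHRASES["cesarean_delivery"][int(rng.integers(0, len(CONCEPT_PHRASES["cesarean_delivery"])))]
        if mode == "cesarean"
        else VAGINAL_PHRASES[int(rng.integers(0, len(VAGINAL_PHRASES)))]
    )
    lines = [
        f"Admission Date: {admit.isoformat()}",
        "Service: OBSTETRICS" + (" (addendum discharge summary)" if addendum else ""),
        "",
        "Hospital Course:",
        f"The patient underwent {mode_phrase}.",
    ]
    if distractor:
        lines.append(f"{distractor[0].upper()}{distractor[1:]}.")
    for cid, on in flags.items():
        if cid == "cesarean_delivery" or not on:
            continue
        bank = CONCEPT_PHRASES[cid]
        phrase = bank[int(rng.integers(0, len(bank)))]
        lines.append(f"Course notable for {phrase}.")
    if ebl_value is not None:
        lines.append(_format_ebl(ebl_value, ebl_fmt or "ml"))
    lines.append("The remainder of the hospital course was uneventful.")
    lines.append("Disposition: discharged home in stable condition with routine followup.")
    return "\n".join(lines)


def generate(config: SynthConfig) -> tuple[list[NoteRecord], SynthTruth, list[GoldAnnotation]]:
    """Generate a corpus with per-note gold labels and per-delivery truth.

    Deterministic given ``config.seed``: the same config yields a
    byte-identical corpus.
    """
    registry = builtin_registry()
    binary_ids = [cid for cid, s in registry.items() if s.kind == "binary"]
    unknown = set(config.concept_prevalence) - set(binary_ids)
    if unknown:
        raise ValueError(f"unknown concepts in prevalence map: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    fmt_names = list(config.ebl_format_weights)
    fmt_w = np.array([config.ebl_format_weights[f] for f in fmt_names], dtype=float)
    fmt_w = fmt_w / fmt_w.sum()
    span_days = (config.end_date - config.start_date).days

    notes: list[NoteRecord] = []
    note_truth: dict[str, NoteTruth] = {}
    deliveries: list[DeliveryTruth] = []
    gold: list[GoldAnnotation] = []

    for di in range(config.n_notes):
        patient_id = f"P{di:05d}"
        admit = config.start_date + timedelta(days=int(rng.integers(0, span_days + 1)))
        mode = "cesarean" if rng.random() < config.cesarean_rate else "vaginal"
        flags = {cid: bool(rng.random() < config.concept_prevalence.get(cid, 0.0)) for cid in binary_ids}
        flags["cesarean_delivery"] = mode == "cesarean"

        # planted EBL: PPH deliveries draw above the mode threshold, others
        # below it (or none); all values are multiples of 50 mL
        is_pph = rng.random() < config.pph_rate
        threshold = (
            config.rule.cesarean_threshold_ml if mode == "cesarean" else config.rule.vaginal_threshold_ml
        )
        if is_pph:
            ebl_value: float | None = float(threshold + 50 * int(rng.integers(1, 31)))
        elif rng.random() < config.p_no_ebl:
            ebl_value = None
        else:
            ebl_value = float(50 * int(rng.integers(2, threshold // 50 + 1)))
        ebl_fmt = str(rng.choice(fmt_names, p=fmt_w)) if ebl_value is not None else None

        distractor = (
            DISTRACTOR_PHRASES[int(rng.integers(0, len(DISTRACTOR_PHRASES)))]
            if rng.random() < config.distractor_rate
            else None
        )

        n_group = 2 if rng.random() < config.multi_note_fraction else 1
        group_note_ids = []
        day = admit
        for j in range(n_group):
            if j > 0:
                day = day + timedelta(days=int(rng.integers(0, config.max_note_gap_days + 1)))
            note_id = f"N{di:05d}-{j}"
            text = _note_text(
                rng, mode, flags, ebl_value, ebl_fmt, distractor if j == 0 else None, day, addendum=j > 0
            )
            if config.misspell_rate > 0 or config.abbrev_rate > 0:
                text = corrupt(
                    text,
                    config.misspell_rate,
                    config.abbrev_rate,
                    seed=int(rng.integers(0, 2**31)),
                    preserve_numbers=True,
                )
            hospital = HOSPITALS[int(rng.integers(0, len(HOSPITALS)))]
            notes.append(
                NoteRecord(
                    note_id=note_id,
                    patient_id=patient_id,
                    note_date=day,
                    hospital=hospital,
                    status="final",
                    department="obstetrics",
                    text=text,
                )
            )
            values = (float(ebl_value),) if ebl_value is not None else ()
            note_truth[note_id] = NoteTruth(concept_flags=dict(flags), ebl_values=values, mode=mode)
            group_note_ids.append(note_id)
            for cid in binary_ids:
                gold.append(GoldAnnotation(note_id=note_id, concept_id=cid, label=flags[cid]))
            gold.append(
                GoldAnnotation(note_id=note_id, concept_id="estimated_blood_loss", values=frozenset(values))
            )

        # delivery-level truth: same EBL restated across notes de-duplicates
        total = float(ebl_value) if ebl_value is not None else 0.0
        pph = classify_pph(total, mode, config.rule)
        sub = nlp_subtype({cid: flags[cid] for cid in SUBTYPE_CONCEPTS})
        deliveries.append(
            DeliveryTruth(
                delivery_id=f"{patient_id}:{admit.isoformat()}",
                patient_id=patient_id,
                note_ids=tuple(group_note_ids),
                mode=mode,
                total_ebl_ml=total,
                pph=pph,
                subtypes=sub.flags(),
                concept_flags=dict(flags),
            )
        )

    return notes, SynthTruth(notes=note_truth, deliveries=tuple(deliveries)), gold


def generate_icd(
    truth: SynthTruth,
    seed: int = 0,
    code_sensitivity: float = 0.5,
    note_dates: Mapping[str, date] | None = None,
) -> list[IcdRecord]:
    """Emit an ICD-9 code table consistent with the planted truth.

    Every delivery gets a normal-delivery inclusion code; PPH deliveries get
    subtype-aligned hemorrhage codes with probability ``code_sensitivity``
    each, emulating claims under-capture of hemorrhage.
    """
    rng = np.random.default_rng(seed)
    subtype_codes = {"tone": "666.14", "tissue": "666.04", "trauma": "665.51", "thrombin": "666.32"}
    records: list[IcdRecord] = []
    for d in truth.deliveries:
        day = date.fromisoformat(d.delivery_id.split(":", 1)[1])
        records.append(IcdRecord(patient_id=d.patient_id, code="650", code_date=day, vocabulary="ICD9"))
        if d.pph:
            emitted = False
            for s in SUBTYPES:
                if d.subtypes.get(s) and rng.random() < code_sensitivity:
                    records.append(
                        IcdRecord(patient_id=d.patient_id, code=subtype_codes[s], code_date=day, vocabulary="ICD9")
                    )
                    emitted = True
            if not emitted and rng.random() < code_sensitivity:
                records.append(
                    IcdRecord(patient_id=d.patient_id, code="666.12", code_date=day, vocabulary="ICD9")
                )
    return records


def truth_report(truth: SynthTruth) -> dict:
    """Aggregate counts over the planted truth (brute-force recountable)."""
    n_notes = len(truth.notes)
    n_del = len(truth.deliveries)
    concept_prev = {}
    if n_notes:
        all_ids = sorted({cid for t in truth.notes.values() for cid in t.concept_flags})
        concept_prev = {
            cid: sum(t.concept_flags[cid] for t in truth.notes.values()) / n_notes for cid in all_ids
        }
    return {
        "n_notes": n_notes,
        "n_deliveries": n_del,
        "concept_prevalence": concept_prev,
        "pph_rate": (sum(d.pph for d in truth.deliveries) / n_del) if n_del else 0.0,
        "cesarean_rate": (sum(d.mode == "cesarean" for d in truth.deliveries) / n_del) if n_del else 0.0,
        "subtype_rates": {
            s: (sum(d.subtypes[s] for d in truth.deliveries) / n_del) if n_del else 0.0 for s in SUBTYPES
        },
    }
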