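"""Four-T subtyping of PPH deliveries: tone, tissue, trauma, thrombin.

The NLP rule engine maps delivery-level concept flags to subtypes; the ICD
baseline maps ICD-9 diagnosis codes through dotted wildcard patterns. A
delivery may carry multiple subtypes. Two guards are intentional:

* laceration signals trauma only when no other subtype (and no other trauma
  trigger) applies — lacerations are common in uncomplicated deliveries;
* 664.x codes signal trauma only when no 666.x code is present, i.e. when no
  other cause of hemorrhage is coded (665.x signals trauma unconditionally).

Thrombin via fresh frozen plasma requires an FFP:RBC unit ratio above 1:1:1.
Note-level concept flags are binary, so by default FFP alone does not trigger
thrombin unless transfusion unit counts are supplied; a permissive switch
accepts the FFP flag alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SubtypeResult",
    "SUBTYPES",
    "TONE_CONCEPTS",
    "TISSUE_CONCEPTS",
    "TRAUMA_CONCEPTS",
    "THROMBIN_CONCEPTS",
    "SUBTYPE_CONCEPTS",
    "nlp_subtype",
    "code_matches",
    "icd_subtype",
    "ICD_SUBTYPE_PATTERNS",
    "subtype_prevalence",
]

SUBTYPES = ("tone", "tissue", "trauma", "thrombin")

TONE_CONCEPTS = ("uterine_atony", "methylergonovine", "carboprost", "misoprostol_uterotonic")
TISSUE_CONCEPTS = ("accreta_spectrum", "retained_products", "dilation_curettage", "manual_extraction_placenta")
#: Unconditional trauma triggers; laceration is handled by the guard.
TRAUMA_CONCEPTS = ("uterine_rupture", "oleary_sutures", "pph_surgical")
THROMBIN_CONCEPTS = ("coagulation_disorders", "platelets", "cryoprecipitate")
LACERATION = "laceration"
FFP = "fresh_frozen_plasma"

#: All concept flags the NLP rule engine reads.
SUBTYPE_CONCEPTS = TONE_CONCEPTS + TISSUE_CONCEPTS + TRAUMA_CONCEPTS + (LACERATION,) + THROMBIN_CONCEPTS + (FFP,)


@dataclass(frozen=True)
class SubtypeResult:
    tone: bool
    tissue: bool
    trauma: bool
    thrombin: bool
    evidence: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    notes: tuple[str, ...] = ()

    def flags(self) -> dict[str, bool]:
        return {"tone": self.tone, "tissue": self.tissue, "trauma": self.trauma, "thrombin": self.thrombin}


def nlp_subtype(
    flags: Mapping[str, bool],
    transfusion_counts: tuple[float, float] | None = None,
    ffp_alone_qualifies: bool = False,
) -> SubtypeResult:
    """Apply the four-T composite definitions to delivery-level concept flags.

    ``transfusion_counts`` is (ffp_units, rbc_units) when available; FFP then
    contributes to thrombin iff ffp_units > rbc_units (ratio above 1:1:1).
    Without counts, FFP alone contributes only under the permissive switch,
    and the skipped check is recorded in ``notes``.
    """
    missing = [c for c in SUBTYPE_CONCEPTS if c not in flags]
    if missing:
        raise ValueError(f"missing subtype-relevant concept flags: {missing}")

    evidence: dict[str, list[str]] = {s: [] for s in SUBTYPES}
    notes: list[str] = []

    for cid in TONE_CONCEPTS:
        if flags[cid]:
            evidence["tone"].append(cid)
    for cid in TISSUE_CONCEPTS:
        if flags[cid]:
            evidence["tissue"].append(cid)
    for cid in THROMBIN_CONCEPTS:
        if flags[cid]:
            evidence["thrombin"].append(cid)
    if flags[FFP]:
        if transfusion_counts is not None:
            ffp_units, rbc_units = transfusion_counts
            if ffp_units > rbc_units:
                evidence["thrombin"].append(FFP)
        elif ffp_alone_qualifies:
            evidence["thrombin"].append(FFP)
        else:
            notes.append("ffp_ratio_check_skipped: no transfusion unit counts")
    for cid in TRAUMA_CONCEPTS:
        if flags[cid]:
            evidence["trauma"].append(cid)

    tone = bool(evidence["tone"])
    tissue = bool(evidence["tissue"])
    thrombin = bool(evidence["thrombin"])
    trauma = bool(evidence["trauma"])
    # laceration guard: evaluated last, fires only when nothing else did
    if flags[LACERATION] and not (tone or tissue or thrombin or trauma):
        trauma = True
        evidence["trauma"].append(LACERATION)

    return SubtypeResult(
        tone=tone,
        tissue=tissue,
        trauma=trauma,
        thrombin=thrombin,
        evidence={s: tuple(v) for s, v in evidence.items()},
        notes=tuple(notes),
    )


def code_matches(code: str, pattern: str) -> bool:
    """Dotted ICD-9 prefix match with trailing ``x`` wildcards.

    Each ``x`` accepts any digit; the code may extend beyond the pattern only
    through the wildcard tail ("any more specific code under it"), so
    ``666.14`` matches ``666.1x`` and ``664.31`` matches ``664.x``. A pattern
    without wildcards requires an exact match.
    """
    if not pattern:
        raise ValueError("empty pattern")
    i = pattern.find("x")
    if i == -1:
        return code == pattern
    literal, wild = pattern[:i], pattern[i:]
    if set(wild) != {"x"}:
        raise ValueError(f"malformed pattern {pattern!r}: wildcards must be final")
    if not code.startswith(literal):
        return False
    remainder = code[len(literal):]
    return bool(remainder) and remainder.isdigit()


#: ICD-9 baseline definitions. The 664.x trauma rule carries the no-666.x guard.
ICD_SUBTYPE_PATTERNS: dict[str, tuple[str, ...]] = {
    "tone": ("666.1x",),
    "tissue": ("666.0x",),
    "trauma": ("665.x", "664.x"),
    "thrombin": ("666.3x",),
}


def icd_subtype(codes: Iterable[str]) -> SubtypeResult:
    """Classify a delivery's ICD-9 code set into the four-T subtypes."""
    codes = set(codes)
    evidence: dict[str, list[str]] = {s: [] for s in SUBTYPES}

    any_666 = any(code_matches(c, "666.x") for c in codes)
    for c in sorted(codes):
        if code_matches(c, "666.1x"):
            evidence["tone"].append(c)
        if code_matches(c, "666.0x"):
            evidence["tissue"].append(c)
        if code_matches(c, "666.3x"):
            evidence["thrombin"].append(c)
        if code_matches(c, "665.x"):
            evidence["trauma"].append(c)
        if code_matches(c, "664.x") and not any_666:
            evidence["trauma"].append(c)

    return SubtypeResult(
        tone=bool(evidence["tone"]),
        tissue=bool(evidence["tissue"]),
        trauma=bool(evidence["trauma"]),
        thrombin=bool(evidence["thrombin"]),
        evidence={s: tuple(v) for s, v in evidence.items()},
    )


def subtype_prevalence(results: Sequence[SubtypeResult]) -> dict[str, float]:
    """Fraction of deliveries with each subtype flag (multi-label, so the
    fractions need not sum to 1)."""
    if not results:
        warnings.warn("no subtype results; prevalence is empty")
        return {}
    n = len(results)
    return {s: sum(getattr(r, s) for r in results) / n for s in SUBTYPES}
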