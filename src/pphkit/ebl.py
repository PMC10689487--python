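"""Estimated-blood-loss post-processing.

Extracted text segments are parsed into numeric mentions with unit hints,
normalized to milliliters, de-duplicated by value, and summed. The rules:

* any maximal numeric token (integer or decimal, optional thousands
  separators) yields one mention; an adjoining unit token (ml, cc, l,
  liters, milliliters — case-insensitive, possibly concatenated as in
  ``800cc``) sets the unit hint;
* liters convert at 1000 mL/L; a unitless value below 10 is assumed to be
  liters (clinicians write "EBL 2" meaning 2 L; no plausible delivery loss is
  under 10 mL), a unitless value of 10 or more is assumed mL;
* equal normalized values within one note are treated as repeated mentions of
  the same loss and counted once; the total is the sum of distinct values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

__all__ = ["EblMention", "EblSummary", "parse_mentions", "normalize_to_ml", "summarize"]

_NUMBER_RE = re.compile(r"\d{1,3}(?:,\d{3})+(?:\.\d+)?|\d+(?:\.\d+)?|\.\d+")
# unit words, longest first so "milliliters" is not read as bare "ml"
_UNIT_RE = re.compile(r"(milliliters?|liters?|mls?|cc|l)", re.IGNORECASE)

_UNIT_MAP = {"milliliter": "ml", "ml": "ml", "cc": "cc", "liter": "l", "l": "l"}


@dataclass(frozen=True)
class EblMention:
    raw: str
    value: float
    unit_hint: str  # ml | cc | l | none


@dataclass(frozen=True)
class EblSummary:
    values_ml: tuple[float, ...]  # distinct normalized values, sorted
    total_ml: float


def _unit_after(segment: str, end: int) -> str:
    """Unit token adjoining the number ending at ``end``, or 'none'.

    A unit separated by one space must be a complete word. A unit concatenated
    directly to the digits may be followed by further letters only for ``cc``
    (covers shorthand like ``500ccf/b``); ``ml``/``l`` concatenated forms may
    take a plural ``s`` but not arbitrary trailing letters, so ``2lbs`` is not
    a liters mention.
    """
    rest = segment[end:]
    spaced = rest.startswith((" ", "\t"))
    rest_stripped = rest[1:] if spaced else rest
    m = _UNIT_RE.match(rest_stripped)
    if not m:
        return "none"
    word = m.group(1).lower()
    unit = _UNIT_MAP[word.rstrip("s") if word not in ("cc",) else word]
    trailing = rest_stripped[m.end() : m.end() + 1]
    if trailing.isalpha() and unit != "cc":
        return "none"
    return unit


def parse_mentions(segments: Iterable[str]) -> list[EblMention]:
    """Every maximal numeric token in each segment becomes one mention;
    non-numeric segments contribute nothing."""
    mentions: list[EblMention] = []
    for seg in segments:
        for m in _NUMBER_RE.finditer(seg):
            value = float(m.group().replace(",", ""))
            mentions.append(EblMention(raw=seg, value=value, unit_hint=_unit_after(seg, m.end())))
    return mentions


def normalize_to_ml(mention: EblMention) -> float:
    """Convert one mention to milliliters (single-digit-liters rule for
    unitless values below 10)."""
    if mention.value < 0:
        raise ValueError("EBL value must be non-negative")
    if mention.unit_hint == "l":
        return mention.value * 1000.0
    if mention.unit_hint in ("ml", "cc"):
        return float(mention.value)
    return mention.value * 1000.0 if mention.value < 10 else float(mention.value)


def summarize(mentions: Iterable[EblMention]) -> EblSummary:
    """Normalize, collapse equal values, and sum."""
    distinct = sorted({normalize_to_ml(m) for m in mentions})
    return EblSummary(values_ml=tuple(distinct), total_ml=float(sum(distinct)))
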