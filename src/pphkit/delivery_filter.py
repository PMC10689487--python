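"""Identify discharge summaries that describe a delivery encounter.

Three approaches are provided and comparable on a labeled sample: a term
(substring) filter tuned for recall, an ICD/DRG code filter linking codes to
the note date within a day window, and a prompted filter that chunks the note
and asks a backend a single yes/no delivery question per chunk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .corpus_io import IcdRecord, NoteRecord
from .extraction import Backend, ExtractionConfig, chunk_note, parse_yes_no, CallContext, _query
from .registry import PLACEHOLDER, ConceptSpec, PromptTemplate
from .evaluation import ConfusionCounts, binary_metrics, macro_f1

__all__ = [
    "DeliveryFilterConfig",
    "DELIVERY_CONCEPT",
    "term_filter",
    "icd_window_filter",
    "prompted_filter",
    "compare_filters",
]

#: Default recall-oriented term list. The trailing space in "labor " is
#: deliberate: it keeps "laborious" from matching while "labor and delivery"
#: still does.
DEFAULT_TERMS = (
    "labor ",
    "delivery",
    "l&d",
    "cesarean section",
    "c-section",
    "estimated edc",
    "pregnancy",
)

#: Placeholder inclusion/exclusion code-prefix sets for the ICD approach. The
#: published enhanced-delivery-identification code list is external to this
#: package; these prefixes (ICD-9 pregnancy/delivery chapters, V27 outcome of
#: delivery, delivery DRGs) are a documented starting point users should
#: replace with their institution's list.
DEFAULT_INCLUSION_PREFIXES = ("64", "65", "66", "67", "V27", "370", "371", "372", "373", "374", "375")
DEFAULT_EXCLUSION_PREFIXES: tuple[str, ...] = ()

WINDOW_CHOICES = (0, 2, 7, 14)


@dataclass(frozen=True)
class DeliveryFilterConfig:
    terms: tuple[str, ...] = DEFAULT_TERMS
    window_days: int = 7
    inclusion_codes: tuple[str, ...] = DEFAULT_INCLUSION_PREFIXES
    exclusion_codes: tuple[str, ...] = DEFAULT_EXCLUSION_PREFIXES

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("terms must be non-empty")


#: Prompted-filter pseudo-concept. The patterns let the pattern backend answer
#: the delivery question; the prompt text is what a generative backend sees.
DELIVERY_CONCEPT = ConceptSpec(
    concept_id="delivery_note",
    display_name="Delivery discharge summary",
    kind="binary",
    prompts=(
        PromptTemplate(
            "Answer the following yes/no question. Does this discharge summary "
            "note mention a woman's delivery? note: " + PLACEHOLDER,
            "yes_no",
        ),
    ),
    patterns=(r"delivery", r"c[\s-]?section", r"cesarean", r"\bl&d\b", r"\blabor\b", r"delivered"),
    description="Used only by the prompted delivery filter.",
)


def term_filter(note: NoteRecord, config: DeliveryFilterConfig | None = None) -> bool:
    """True iff any term occurs as a case-insensitive substring of the text."""
    config = config or DeliveryFilterConfig()
    text = note.text.lower()
    return any(term.lower() in text for term in config.terms)


def _matches_any(code: str, prefixes: Iterable[str]) -> bool:
    return any(code.startswith(p) for p in prefixes)


def icd_window_filter(
    note: NoteRecord,
    codes: Sequence[IcdRecord],
    config: DeliveryFilterConfig | None = None,
) -> bool:
    """True iff the note's patient has at least one inclusion-prefix code and
    no exclusion-prefix code dated within ``window_days`` of the note
    (boundary inclusive)."""
    config = config or DeliveryFilterConfig()
    if note.note_date is None:
        raise ValueError(f"note {note.note_id} has no date")
    has_inclusion = False
    for rec in codes:
        if rec.patient_id != note.patient_id:
            continue
        if rec.code_date is None:
            raise ValueError(f"ICD record {rec.code} has no date")
        if abs((rec.code_date - note.note_date).days) > config.window_days:
            continue
        if _matches_any(rec.code, config.exclusion_codes):
            return False
        if _matches_any(rec.code, config.inclusion_codes):
            has_inclusion = True
    return has_inclusion


def prompted_filter(
    note: NoteRecord,
    backend: Backend,
    config: ExtractionConfig | None = None,
) -> bool:
    """Chunk the note (512-token windows, no overlap by default) and ask the
    delivery question per chunk; true iff any chunk parses positive."""
    config = config or ExtractionConfig(window_tokens=512, overlap_tokens=0)
    prompt = DELIVERY_CONCEPT.prompts[0]
    for chunk in chunk_note(note, config):
        ctx = CallContext(note.note_id, DELIVERY_CONCEPT.concept_id, chunk, 0, "yes_no")
        rendered = prompt.template_text.replace(PLACEHOLDER, chunk.text, 1)
        if parse_yes_no(_query(backend, rendered, ctx)) == "positive":
            return True
    return False


def compare_filters(
    notes: Sequence[NoteRecord],
    gold: Mapping[str, bool],
    filters: Mapping[str, Callable[[NoteRecord], bool]],
) -> pd.DataFrame:
    """Evaluate each named filter against note-level gold labels.

    Returns one row per approach with sensitivity, specificity, PPV, binary
    F1, macro F1 and accuracy.
    """
    missing = [n.note_id for n in notes if n.note_id not in gold]
    if missing:
        raise ValueError(f"gold labels missing for notes: {missing[:5]}")
    rows = []
    for name, fn in filters.items():
        c = ConfusionCounts(0, 0, 0, 0)
        tp = fp = fn_ = tn = 0
        for note in notes:
            pred, truth = fn(note), gold[note.note_id]
            tp += pred and truth
            fp += pred and not truth
            fn_ += (not pred) and truth
            tn += (not pred) and (not truth)
        c = ConfusionCounts(tp=tp, fp=fp, fn=fn_, tn=tn)
        metrics = binary_metrics(c)
        metrics["macro_f1"] = macro_f1(c)
        rows.append({"approach": name, **metrics})
    return pd.DataFrame(rows).set_index("approach")
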