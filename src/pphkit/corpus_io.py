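"""Data model and I/O for discharge summaries, ICD code tables and gold labels.

Canonical on-disk formats are JSON-Lines for notes and annotations and CSV for
ICD code tables; CSV is also accepted for notes as a convenience. Dates are
day-granular ISO-8601 strings on disk and :class:`datetime.date` in memory.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "NoteRecord",
    "IcdRecord",
    "GoldAnnotation",
    "CleaningReport",
    "read_notes",
    "write_notes",
    "read_icd",
    "write_icd",
    "read_annotations",
    "write_annotations",
    "clean_corpus",
    "write_table",
]

NOTE_FIELDS = ("note_id", "patient_id", "note_date", "hospital", "status", "department", "text")
ICD_FIELDS = ("patient_id", "code", "code_date", "vocabulary")
VOCABULARIES = frozenset({"ICD9", "ICD10", "DRG"})
STATUSES = frozenset({"final", "draft"})


class CorpusFormatError(ValueError):
    """Raised when an input file violates the corpus schema."""


def _parse_date(value: str | date, where: str) -> date:
    if isinstance(value, date):
        return value
    try:
        return datetime.strptime(str(value).strip()[:10], "%Y-%m-%d").date()
    except ValueError as exc:
        raise CorpusFormatError(f"{where}: unparseable date {value!r} (expected YYYY-MM-DD)") from exc


@dataclass(frozen=True)
class NoteRecord:
    """One discharge summary."""

    note_id: str
    patient_id: str
    note_date: date
    hospital: str
    status: str = "final"
    department: str = ""
    text: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise CorpusFormatError(
                f"note {self.note_id}: status must be one of {sorted(STATUSES)}, got {self.status!r}"
            )


@dataclass(frozen=True)
class IcdRecord:
    """One coded diagnosis / DRG row for a patient on a date."""

    patient_id: str
    code: str
    code_date: date
    vocabulary: str

    def __post_init__(self) -> None:
        if not self.code:
            raise CorpusFormatError(f"ICD record for patient {self.patient_id}: empty code")
        if self.vocabulary not in VOCABULARIES:
            raise CorpusFormatError(
                f"ICD record {self.code}: vocabulary must be one of {sorted(VOCABULARIES)}, "
                f"got {self.vocabulary!r} (never inferred from code shape)"
            )


@dataclass(frozen=True)
class GoldAnnotation:
    """Gold label for one (note, concept).

    Exactly one of ``label`` (binary concepts) or ``values`` (the measurement
    concept, normalized mL) is populated.
    """

    note_id: str
    concept_id: str
    label: bool | None = None
    values: frozenset[float] | None = None

    def __post_init__(self) -> None:
        if (self.label is None) == (self.values is None):
            raise CorpusFormatError(
                f"annotation ({self.note_id}, {self.concept_id}): exactly one of "
                "label or values must be set"
            )
        if self.values is not None and not isinstance(self.values, frozenset):
            object.__setattr__(self, "values", frozenset(self.values))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _require(row: dict, fields: Sequence[str], where: str) -> None:
    for f in fields:
        if row.get(f) in (None, ""):
            if f in ("text", "department"):  # may legitimately be empty on read
                continue
            raise CorpusFormatError(f"{where}: missing required field {f!r}")


def _iter_rows(path: str | Path, format: str) -> Iterable[tuple[int, dict]]:
    path = Path(path)
    if format == "jsonl":
        with path.open() as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    yield i, json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{path}:{i}: malformed JSON ({exc})") from exc
    elif format == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return
            for i, row in enumerate(reader, start=2):  # header is line 1
                yield i, row
    else:
        raise ValueError(f"unknown format {format!r} (expected 'jsonl' or 'csv')")


def read_notes(path: str | Path, format: str = "jsonl") -> list[NoteRecord]:
    """Read a note corpus, enforcing schema and note_id uniqueness."""
    notes: list[NoteRecord] = []
    seen: set[str] = set()
    for lineno, row in _iter_rows(path, format):
        where = f"{path}:{lineno}"
        _require(row, NOTE_FIELDS, where)
        nid = str(row["note_id"])
        if nid in seen:
            raise CorpusFormatError(f"{where}: duplicate note_id {nid!r}")
        seen.add(nid)
        notes.append(
            NoteRecord(
                note_id=nid,
                patient_id=str(row["patient_id"]),
                note_date=_parse_date(row["note_date"], where),
                hospital=str(row["hospital"]),
                status=str(row.get("status") or "final"),
                department=str(row.get("department") or ""),
                text=str(row.get("text") or ""),
            )
        )
    return notes


def write_notes(notes: Iterable[NoteRecord], path: str | Path, format: str = "jsonl") -> None:
    rows = [
        {**asdict(n), "note_date": n.note_date.isoformat()}
        for n in notes
    ]
    _write_rows(rows, path, format, NOTE_FIELDS)


def read_icd(path: str | Path, format: str = "csv") -> list[IcdRecord]:
    records = []
    for lineno, row in _iter_rows(path, format):
        where = f"{path}:{lineno}"
        _require(row, ICD_FIELDS, where)
        records.append(
            IcdRecord(
                patient_id=str(row["patient_id"]),
                code=str(row["code"]),
                code_date=_parse_date(row["code_date"], where),
                vocabulary=str(row["vocabulary"]),
            )
        )
    return records


def write_icd(records: Iterable[IcdRecord], path: str | Path, format: str = "csv") -> None:
    rows = [{**asdict(r), "code_date": r.code_date.isoformat()} for r in records]
    _write_rows(rows, path, format, ICD_FIELDS)


def read_annotations(path: str | Path, known_concepts: Iterable[str] | None = None) -> list[GoldAnnotation]:
    """Read gold annotations; if ``known_concepts`` is given, unknown concept_ids error."""
    known = set(known_concepts) if known_concepts is not None else None
    out = []
    for lineno, row in _iter_rows(path, "jsonl"):
        where = f"{path}:{lineno}"
        _require(row, ("note_id", "concept_id"), where)
        cid = str(row["concept_id"])
        if known is not None and cid not in known:
            raise CorpusFormatError(f"{where}: unknown concept_id {cid!r}")
        label = row.get("label")
        values = row.get("values")
        out.append(
            GoldAnnotation(
                note_id=str(row["note_id"]),
                concept_id=cid,
                label=None if label is None else bool(label),
                values=None if values is None else frozenset(float(v) for v in values),
            )
        )
    return out


def write_annotations(annotations: Iterable[GoldAnnotation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for a in annotations:
            row: dict = {"note_id": a.note_id, "concept_id": a.concept_id}
            if a.label is not None:
                row["label"] = a.label
            else:
                row["values"] = sorted(a.values or ())
            fh.write(json.dumps(row) + "\n")


def write_table(rows: Iterable[dict], path: str | Path, format: str = "csv",
                fields: Sequence[str] | None = None) -> None:
    """Generic row writer used by pipeline stages."""
    rows = list(rows)
    if fields is None:
        fields = list(rows[0].keys()) if rows else []
    _write_rows(rows, path, format, fields)


def _write_rows(rows: list[dict], path: str | Path, format: str, fields: Sequence[str]) -> None:
    path = Path(path)
    if format == "jsonl":
        with path.open("w") as fh:
            for row in rows:
                fh.write(json.dumps({f: row.get(f) for f in fields}) + "\n")
    elif format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(fields))
            writer.writeheader()
            for row in rows:
                writer.writerow({f: row.get(f) for f in fields})
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

@dataclass
class CleaningReport:
    """Counts of notes removed by each cleaning rule."""

    n_input: int = 0
    n_output: int = 0
    removed_draft: int = 0
    removed_department: int = 0
    removed_duplicate: int = 0
    removed_empty: int = 0

    def total_removed(self) -> int:
        return self.removed_draft + self.removed_department + self.removed_duplicate + self.removed_empty


def clean_corpus(
    notes: Sequence[NoteRecord],
    drop_drafts: bool = True,
    drop_departments: Iterable[str] = ("emergency",),
    dedupe: bool = True,
) -> tuple[list[NoteRecord], CleaningReport]:
    """Apply note-level cleaning: drop drafts, drop listed departments, and
    collapse exact-duplicate texts within a patient keeping the earliest note.

    Department matching is case-insensitive. Returns the kept notes (input
    order preserved) and a report whose removal counts sum to
    ``n_input - n_output``.
    """
    report = CleaningReport(n_input=len(notes))
    drop_depts = {d.lower() for d in drop_departments}

    kept: list[NoteRecord] = []
    for n in notes:
        if not n.text.strip():
            report.removed_empty += 1
            continue
        if drop_drafts and n.status == "draft":
            report.removed_draft += 1
            continue
        if n.department.lower() in drop_depts:
            report.removed_department += 1
            continue
        kept.append(n)

    if dedupe:
        # earliest note_date wins within (patient_id, exact text); ties broken
        # by note_id for determinism
        best: dict[tuple[str, str], NoteRecord] = {}
        for n in kept:
            key = (n.patient_id, n.text)
            cur = best.get(key)
            if cur is None or (n.note_date, n.note_id) < (cur.note_date, cur.note_id):
                best[key] = n
        winners = {id(n) for n in best.values()}
        deduped = [n for n in kept if id(n) in winners]
        report.removed_duplicate = len(kept) - len(deduped)
        kept = deduped

    report.n_output = len(kept)
    return kept, report
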