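"""Metrics and paired-comparison statistics.

Binary concepts are scored with sensitivity, specificity, PPV, binary F1 and
accuracy from a confusion table; the measurement concept is scored with
value-level sensitivity/PPV pooled over notes plus note-level exact-set
accuracy. Paired classifier comparisons use the McNemar test (exact binomial
below 25 discordant pairs, continuity-corrected chi-square above).

Undefined metric denominators yield NaN, never a silent 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from . import ebl as _ebl

__all__ = [
    "ConfusionCounts",
    "PairedOutcomes",
    "binary_metrics",
    "macro_f1",
    "extraction_metrics",
    "mcnemar",
    "concept_report",
    "ebl_icd_crosstab",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PairedOutcomes:
    """Counts of items by (method A correct?, method B correct?)."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("paired counts must be non-negative")


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def binary_metrics(c: ConfusionCounts) -> dict[str, float]:
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    if math.isnan(ppv) or math.isnan(sens) or (ppv + sens) == 0:
        f1 = math.nan
    else:
        f1 = 2 * ppv * sens / (ppv + sens)
    acc = _ratio(c.tp + c.tn, c.total)
    return {"sensitivity": sens, "specificity": spec, "ppv": ppv, "binary_f1": f1, "accuracy": acc}


def macro_f1(c: ConfusionCounts) -> float:
    """Unweighted mean of the positive-class and negative-class F1 scores."""
    pos = binary_metrics(c)["binary_f1"]
    neg = binary_metrics(ConfusionCounts(tp=c.tn, fp=c.fn, fn=c.fp, tn=c.tp))["binary_f1"]
    return (pos + neg) / 2


def extraction_metrics(
    pred: Mapping[str, Iterable[float]],
    gold: Mapping[str, Iterable[float]],
    note_accuracy_mode: str = "set",
) -> dict[str, float]:
    """Value-extraction metrics pooled over a shared note universe.

    sensitivity = |pred ∩ gold| / |gold| and ppv = |pred ∩ gold| / |pred|,
    both pooled over notes. ``note_accuracy`` is the fraction of notes whose
    predicted value set equals the gold set exactly (mode "set"); mode
    "total" instead compares the sums of the value sets.
    """
    if set(pred) != set(gold):
        raise ValueError("pred and gold must cover the same notes")
    tp = n_gold = n_pred = 0
    correct_notes = 0
    for nid in gold:
        p, g = set(pred[nid]), set(gold[nid])
        tp += len(p & g)
        n_gold += len(g)
        n_pred += len(p)
        if note_accuracy_mode == "set":
            correct_notes += p == g
        elif note_accuracy_mode == "total":
            correct_notes += sum(p) == sum(g)
        else:
            raise ValueError(f"unknown note_accuracy_mode {note_accuracy_mode!r}")
    return {
        "sensitivity": _ratio(tp, n_gold),
        "ppv": _ratio(tp, n_pred),
        "note_accuracy": _ratio(correct_notes, len(gold)),
    }


def mcnemar(p: PairedOutcomes, mode: str = "auto") -> dict:
    """McNemar paired test on the discordant counts b = n10, c = n01.

    exact: two-sided binomial test of b successes in b+c trials at 0.5.
    chi2cc: continuity-corrected statistic (|b-c|-1)^2/(b+c) against
    chi-square with 1 df. auto uses exact when b+c < 25.
    """
    b, c = p.n10, p.n01
    if mode not in ("auto", "exact", "chi2cc"):
        raise ValueError(f"unknown mode {mode!r}")
    used = mode if mode != "auto" else ("exact" if b + c < 25 else "chi2cc")
    if b + c == 0:
        return {"statistic": None, "p_value": 1.0, "mode_used": used}
    table = [[p.n11, b], [c, p.n00]]
    if used == "exact":
        res = _sm_mcnemar(table, exact=True)
        return {"statistic": None, "p_value": min(1.0, float(res.pvalue)), "mode_used": used}
    res = _sm_mcnemar(table, exact=False, correction=True)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue), "mode_used": used}


def concept_report(
    calls: Sequence,
    gold: Sequence,
    registry: Mapping,
) -> pd.DataFrame:
    """Per-concept performance table.

    One row per concept with gold labels: binary concepts report the
    confusion-derived metrics, the measurement concept reports value
    sensitivity/PPV and note accuracy (its values normalized to mL first).
    ``n`` is the gold positive count (binary) or the number of notes with a
    non-empty gold value set (measurement). Concepts without gold are omitted
    with a warning.
    """
    call_index: dict[tuple[str, str], object] = {(c.note_id, c.concept_id): c for c in calls}
    by_concept: dict[str, list] = {}
    for g in gold:
        by_concept.setdefault(g.concept_id, []).append(g)

    rows = []
    for cid, spec in registry.items():
        anns = by_concept.get(cid)
        if not anns:
            warnings.warn(f"concept {cid} has no gold annotations; omitted from report")
            continue
        if spec.kind == "binary":
            tp = fp = fn = tn = 0
            for a in anns:
                call = call_index.get((a.note_id, cid))
                if call is None:
                    raise ValueError(f"no call for annotated ({a.note_id}, {cid})")
                pred, truth = bool(call.label), bool(a.label)
                tp += pred and truth
                fp += pred and not truth
                fn += (not pred) and truth
                tn += (not pred) and (not truth)
            m = binary_metrics(ConfusionCounts(tp, fp, fn, tn))
            rows.append({"concept_id": cid, "kind": "binary", "n": tp + fn, **m})
        else:
            pred_map: dict[str, set] = {}
            gold_map: dict[str, set] = {}
            for a in anns:
                call = call_index.get((a.note_id, cid))
                if call is None:
                    raise ValueError(f"no call for annotated ({a.note_id}, {cid})")
                mentions = _ebl.parse_mentions(call.segments or ())
                pred_map[a.note_id] = set(_ebl.summarize(mentions).values_ml)
                gold_map[a.note_id] = set(a.values or ())
            m = extraction_metrics(pred_map, gold_map)
            n_pos = sum(1 for v in gold_map.values() if v)
            rows.append({"concept_id": cid, "kind": "measurement", "n": n_pos, **m})
    return pd.DataFrame(rows).set_index("concept_id")


def ebl_icd_crosstab(
    assessments: Sequence,
    icd_records: Sequence,
    bin_edges: Sequence[float],
    pph_code_prefixes: Iterable[str],
    window_days: int = 7,
) -> pd.DataFrame:
    """Proportion of deliveries carrying a PPH code, per extracted-EBL bin.

    Deliveries with no extracted EBL form their own bin. A delivery counts as
    coded when its patient has at least one code with a matching prefix dated
    within ``window_days`` of any of the delivery's note dates.
    """
    prefixes = tuple(pph_code_prefixes)
    by_patient: dict[str, list] = {}
    for rec in icd_records:
        by_patient.setdefault(rec.patient_id, []).append(rec)

    labels = (
        ["no EBL", f"< {bin_edges[0]:g}"]
        + [f"[{bin_edges[i]:g}, {bin_edges[i + 1]:g})" for i in range(len(bin_edges) - 1)]
        + [f">= {bin_edges[-1]:g}"]
    )
    counts = {lab: [0, 0] for lab in labels}  # [n, n_coded]

    for a in assessments:
        if not a.ebl_values:
            lab = "no EBL"
        else:
            lab = labels[1 + int(np.digitize(a.total_ebl_ml, bin_edges))]
        coded = any(
            rec.code.startswith(prefixes)
            and any(abs((rec.code_date - d).days) <= window_days for d in a.note_dates)
            for rec in by_patient.get(a.patient_id, ())
        )
        counts[lab][0] += 1
        counts[lab][1] += coded
    rows = [
        {"ebl_bin": lab, "n": n, "n_coded": k, "proportion": _ratio(k, n)}
        for lab, (n, k) in counts.items()
    ]
    return pd.DataFrame(rows).set_index("ebl_bin")
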