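# pphkit

Zero-shot **extract-then-phenotype** toolkit for postpartum hemorrhage (PPH)
from obstetric discharge summaries.

PPH — excessive bleeding after childbirth — is the leading cause of severe
maternal morbidity, yet claims codes capture it poorly. `pphkit` implements a
two-step alternative for researchers working with EHR notes: first extract 24
granular hemorrhage-related concepts from free text (uterine atony,
uterotonic drugs, transfusion products, retained products of conception,
estimated blood loss, ...), then compose them into an interpretable phenotype
and etiologic subtypes, so that every positive call can be traced back to the
concept and text chunk that produced it.

## What it does

1. **Concept extraction.** Each note is tokenized and split into 512-token
   windows overlapping by 128 tokens. For every (chunk × prompt) pair a
   *backend* answers a yes/no question ("Does the following discharge summary
   mention uterine atony during the current delivery? note: ...") or extracts
   a value (estimated blood loss, with an `unanswerable` fallback). Chunk
   answers aggregate by any-positive OR (binary) or set union (extraction).
   Backends are pluggable: a deterministic regex baseline, a seeded mock for
   testing, and an optional adapter for a local instruction-tuned
   seq2seq model (`pip install pphkit[model]`).
2. **EBL normalization.** Extracted segments are parsed for numeric blood-loss
   mentions in heterogeneous formats (`800 mL`, `800cc`, `1.5 L`, bare `800`,
   concatenated `500ccf/b`), converted to mL (unitless values < 10 are read
   as liters), de-duplicated by value within a delivery, and summed.
3. **Phenotyping.** Notes group into deliveries (same patient, dates chaining
   within 7 days). A delivery is PPH when total EBL > 500 mL (vaginal) or
   > 1000 mL (cesarean); the current ≥ 1000 mL-regardless-of-mode definition
   is a one-line preset.
4. **Subtyping (the four T's).** Multi-label rules assign *tone* (atony or
   uterotonic administration), *tissue* (accreta spectrum, retained products,
   D&C, manual extraction), *trauma* (uterine rupture, O'Leary sutures,
   surgical bleeding, or laceration when nothing else explains the
   hemorrhage), and *thrombin* (DIC, platelet or cryoprecipitate transfusion,
   FFP above a 1:1:1 ratio with red cells). An ICD-9 baseline maps dotted
   wildcard code patterns (tone `666.1x`, tissue `666.0x`, thrombin `666.3x`,
   trauma `665.x` or `664.x`-if-no-`666.x`).
5. **Evaluation.** Per-concept sensitivity/specificity/PPV/F1/accuracy,
   value-level extraction metrics, McNemar paired comparisons, and an
   EBL-bin × ICD-code cross-tabulation.

Because real obstetric notes are protected health information, the package
ships a **synthetic corpus generator** (`pphkit.synthgen`) that plants
concepts, blood-loss values, misspellings, abbreviations and polysemy
distractors with full ground truth — the substrate for all tests.

## Worked example

```python
from pphkit import (SynthConfig, assess_deliveries, builtin_registry,
                    pattern_backend, run_corpus)
from pphkit.synthgen import generate

registry = builtin_registry()                       # the 24 concepts
notes, truth, gold = generate(SynthConfig(n_notes=6, seed=6))
print(notes[1].text)
```

```
Admission Date: 2005-05-31
Service: OBSTETRICS

Hospital Course:
The patient underwent normal spontaneous vaginal delivery of a liveborn infant.
Course notable for course complicated by PPH.
Course notable for cryoprecipitate transfused for low fibrinogen.
Estimated blood loss was 1150 mL.
The remainder of the hospital course was uneventful.
Disposition: discharged home in stable condition with routine followup.
```

```python
calls = run_corpus(notes, registry, pattern_backend(registry))
for a in assess_deliveries(notes, calls):
    print(a.delivery_id, a.mode, a.total_ebl_ml, a.pph)
```

```
P00000:2005-09-17 vaginal 0.0 False
P00001:2005-05-31 vaginal 1150.0 True
P00002:2007-02-18 vaginal 350.0 False
P00003:2008-02-19 cesarean 1000.0 False
P00004:2002-08-11 cesarean 850.0 False
P00005:2001-01-02 vaginal 400.0 False
```

The second delivery documents 1150 mL after a vaginal delivery and is
flagged PPH; note that the cesarean at exactly 1000 mL is *not* flagged —
the thresholds are strict. The same objects expose per-concept evidence
(`a.concept_flags`) for subtyping with `pphkit.nlp_subtype` (here the PPH
delivery carries a cryoprecipitate transfusion, a thrombin trigger).

A command-line interface mirrors the library:

```bash
pph synth --out-dir corpus/ --n-notes 500 --seed 1
pph extract --notes corpus/notes.jsonl --out calls.jsonl --backend pattern
pph phenotype --notes corpus/notes.jsonl --calls calls.jsonl --out deliveries.jsonl
pph subtype --deliveries deliveries.jsonl --out subtypes.jsonl
pph evaluate --calls calls.jsonl --gold corpus/gold.jsonl --out report.csv
```

## Layout

```
src/pphkit/
  corpus_io.py        note / ICD / annotation data model and I/O, cleaning
  registry.py         the 24 concepts: prompts, patterns, phrase banks
  extraction.py       tokenize, chunk, prompt, parse, aggregate; backends
  ebl.py              blood-loss parsing, normalization, de-duplication
  delivery_filter.py  term / ICD-window / prompted delivery-note filters
  phenotyping.py      note grouping, mode inference, PPH rule
  subtyping.py        four-T rule engines (NLP and ICD)
  evaluation.py       metrics, McNemar, report tables
  synthgen.py         synthetic corpus generator with planted truth
  pipeline.py, cli.py orchestration and the `pph` command
```

See `docs/methods.md` for the model, parameter and design details.
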