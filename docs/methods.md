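# Methods

## The extract-then-phenotype model

`pphkit` treats PPH phenotyping as composition of two separable problems.

**Concept extraction** is framed per (note, concept). A note is tokenized and
split into overlapping token windows; each window is substituted into one or
more prompt templates and sent to a backend, which returns short generated
text. For binary concepts the response parses to positive / negative /
unparseable (case-insensitive prefix match on "yes"/"no" after stripping
leading non-letters; unparseable counts as negative, the conservative choice
that never inflates positives). The note label is the OR over all
(chunk × prompt) outcomes; for the single measurement concept (estimated
blood loss) the note result is the set union of non-fallback response
segments. Chained prompts implement concepts whose surface forms diverge
(placenta accreta spectrum asks separately about accreta, increta and
percreta; similarly misoprostol-as-uterotonic, coagulation disorders, and
surgically caused hemorrhage).

**Phenotyping** is pure rule application over extracted values: a delivery is
PPH when the summed, de-duplicated EBL strictly exceeds 500 mL (vaginal) or
1000 mL (cesarean) — the definition in clinical use before 2018; the
current ≥ 1000 mL-any-mode rule is the `acog2017` preset. Subtypes follow
the four-T etiology rules described in the README. Every decision carries
its evidence (triggering concept ids or codes, per-chunk provenance), which
is the point of the two-step design: a flagged delivery can be audited
concept by concept.

## Chunking parameters

* `window_tokens` = 512, `overlap_tokens` = 128 (so the window advances
  384 tokens per step). The published description of this pipeline gives a
  512-token window with a "stride" of 128; we read stride as *overlap*,
  the dominant sliding-window convention in the transformer ecosystem. The
  alternative reading (step = 128) is one config change away.
* Chunk arithmetic: chunk *i* covers tokens `[i·step, i·step + window)`
  clipped to the note length; the windows cover every token, and an empty
  note produces no chunks (never one empty chunk).
* The default tokenizer splits on whitespace and punctuation runs and keeps
  character offsets; it is a pluggable contract so a model-specific
  tokenizer can be swapped in when using a generative backend. Offsets are
  exact: slicing the note by a token's span returns the token.
* Decoding defaults for the generative adapter: greedy, `max_new_tokens` = 5,
  temperature 1.0, batch size 48. None of these affect the deterministic
  backends.

## Backends

* **pattern** — the regex baseline. Ignores the rendered prompt, matches the
  chunk against the concept's shipped pattern set (binary) or returns the
  captured value span(s) (measurement). Deterministic; the reference
  implementation for all end-to-end tests.
* **mock** — replays a planted truth table with label noise. The flip
  decision is made once per (note_id, concept_id) from a stable hash of the
  seed rather than per call: under any-positive aggregation, per-call flips
  would give a truth-positive concept with *k* prompts a survival
  probability of 1 − ε^k instead of 1 − ε, destroying the property that the
  note-level error rate equals the flip rate. Per-pair flipping keeps
  measured sensitivity at exactly 1 − ε in expectation regardless of chunk
  and prompt counts, which is what the noisy-recovery tests rely on. Flipped
  measurement calls answer the fallback token (the mock cannot invent a
  plausible wrong volume).
* **generative** — optional adapter for a local instruction-tuned seq2seq
  model; constructing it without the `transformers`/`torch` extras raises an
  ImportError with an install hint. It is never required by any test, and a
  backend failure anywhere is a hard error carrying the chunk index —
  phenotyping on silently partial extractions is unsafe.

## EBL normalization

Numbers are maximal numeric tokens (decimals, optional thousands
separators). Unit detection accepts ml / cc / l / liters / milliliters,
case-insensitive, spaced or concatenated; a concatenated unit followed by
further letters is accepted only for `cc` (covers shorthand like
`500ccf/b`), so `2lbs` is not read as 2 liters, and a spaced unit must be a
complete word, so "2 large clots" is not a liters mention. Unitless values
below 10 are read as liters (clinicians write "EBL 2"); 10 and above as mL —
no plausible delivery loss is under 10 mL or over 10 L. This rule is
deliberately discontinuous at 10, so monotonicity of normalization holds
within each regime, not across the boundary. Equal normalized values within
one delivery collapse to a single mention before summing (a second note for
the same delivery typically restates the same loss); numeric ranges
("400-600") keep both endpoints when unequal. Genuinely repeated identical
losses are therefore under-counted — unknowable from text alone.

## Delivery grouping

Notes of one patient whose dates chain with gaps ≤ 7 days form one delivery
(configurable; a caller-supplied grouping bypasses it). Day granularity is
used throughout; time of day is discarded on write. The delivery mode is
cesarean iff the cesarean-delivery concept fires on any note of the group.

## The synthetic generator

The generator emulates the *structural* features of obstetric discharge
summaries that this pipeline is sensitive to, not clinical fluency:

* **Concept mentions** sample from per-concept phrase banks shared with the
  registry's pattern sets. Per-note concept prevalences default to the
  concept mix of a PPH-enriched annotated note sample (e.g. laceration 0.36,
  uterine atony 0.09, uterine rupture 0.004); cesarean rate 0.32.
* **EBL surface formats** at fixed weights: `800 mL` (0.35), `800cc` (0.30),
  liters (0.10, only for values divisible by 100), bare number (0.15),
  concatenated `800ccf/b` shorthand (0.10). Planted values are multiples of
  50 mL; PPH deliveries draw uniformly from (threshold, threshold + 1500],
  non-PPH from [100, threshold], with 15% documenting no EBL. The planted
  PPH rate defaults to 0.10.
* **Traps**: 10% of deliveries get a polysemy distractor ("artificial
  rupture of membranes", "misoprostol for cervical ripening") that must not
  fire the corresponding concept. Misspelling and abbreviation corruption
  are off by default and never perturb numeric tokens when enabled with
  number preservation.
* **Multi-note deliveries**: 15% of deliveries emit a second note 0–3 days
  later restating the same concepts and the same blood loss, exercising the
  cross-note de-duplication path. `n_notes` counts deliveries, so the total
  note count exceeds it by the restatement fraction.
* Truth is self-consistent by construction — delivery PPH flags are computed
  by the phenotype rule on planted totals, subtype flags by the NLP subtype
  rule on planted concept flags — and the tests re-derive both
  independently.

**What passing clean-corpus tests shows** is that the pipeline machinery
(chunking, aggregation, parsing, grouping, rules) is exact when every
surface form is covered by the pattern bank. It does **not** show that the
pattern sets, or any backend, generalize to real clinical prose: real notes
carry negation, templated flowsheets, OCR noise, and phrasings outside any
bank. Held-out variant phrases and the corruption operators exist to probe
that gap, not to close it.

## Statistics

McNemar's test compares paired classifiers on their discordant counts
b = n10, c = n01: exact two-sided binomial at 0.5 when b + c < 25, else the
continuity-corrected chi-square (|b−c|−1)²/(b+c) on 1 df (both callable
explicitly; the threshold is standard practice, the original report of this
pipeline does not state its variant). b + c = 0 returns p = 1. The
implementation delegates to statsmodels; the tests verify it against a
direct binomial-tail sum exhaustively for b + c ≤ 20 and against the closed
form. Undefined metric denominators (e.g. PPV with no positive predictions)
are NaN, never 0. Note-level EBL accuracy means exact set equality of
normalized values; total-sum equality is available as a switch since the
phrase "extracting the correct values" is ambiguous between the two.

## Thrombin and FFP

The thrombin definition references fresh frozen plasma "in ratio with red
blood cells higher than 1:1:1", but note-level concept flags are binary.
Default behavior: FFP contributes to thrombin only when transfusion unit
counts are supplied and ffp_units > rbc_units; without counts the check is
skipped and recorded in the result's notes (DIC, platelets and
cryoprecipitate still trigger). A permissive switch accepts the FFP flag
alone. This is faithful to the printed ratio while honest about missing
unit data.

## Problem sizes

The clean end-to-end check runs 500 deliveries (~575 notes) with the pattern
backend; the noisy-recovery check runs 2000 single-note deliveries with a
10% flip mock; exhaustive oracles cover 4096 subtype flag combinations and
1024 ICD code subsets. These sizes give binomial standard errors small
enough for 3-SD acceptance bands while keeping the whole suite around ten
seconds.

## Known limitations

* No negation or temporality handling: "no evidence of uterine rupture"
  would fire the pattern backend. The prompt-based backends are expected to
  do better; the package does not quantify this.
* The ICD delivery-filter inclusion list and the PPH ICD code sets for the
  cross-tabulation are documented placeholders; the published code lists
  live outside this package and should be supplied by the user.
* Secondary / delayed PPH is out of scope (discharge-summary-scoped, primary
  PPH only); ICD-10 → ICD-9 conversion is not provided.
* The note→delivery grouping rule (7-day chaining) is our choice; the
  original cohort's grouping procedure is unpublished.
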