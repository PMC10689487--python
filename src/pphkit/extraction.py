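"""Chunked zero-shot extraction engine.

A note is tokenized, split into overlapping token windows, and each
(chunk x prompt) pair is sent to a backend. Per-chunk answers are aggregated
to the note level: any-positive OR for binary concepts, set union of extracted
segments for the measurement concept. Backends are pluggable; the package
ships a deterministic pattern backend, a seeded mock backend for testing, and
an optional adapter for a local instruction-tuned generative model.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Mapping, Protocol, Sequence

from .corpus_io import NoteRecord
from .registry import ConceptSpec, Registry, render_prompt

__all__ = [
    "ExtractionConfig",
    "Token",
    "Chunk",
    "BackendResponse",
    "CallContext",
    "ConceptCall",
    "Backend",
    "BackendError",
    "tokenize",
    "simple_tokenizer",
    "chunk_note",
    "parse_yes_no",
    "run_binary_concept",
    "run_extraction_concept",
    "run_concept",
    "run_corpus",
    "PatternBackend",
    "pattern_backend",
    "MockBackend",
    "mock_backend",
    "generative_backend",
    "write_calls",
    "read_calls",
]

POSITIVE, NEGATIVE, UNPARSEABLE = "positive", "negative", "unparseable"
FALLBACK_TOKEN = "unanswerable"


@dataclass(frozen=True)
class ExtractionConfig:
    """Windowing and decoding parameters.

    Defaults mirror the reference setup: 512-token windows overlapping by 128
    tokens (step 384), greedy decoding, at most 5 new tokens, temperature 1.0,
    batch size 48. The decoding fields only affect the generative backend.
    """

    window_tokens: int = 512
    overlap_tokens: int = 128
    max_new_tokens: int = 5
    decode_mode: str = "greedy"
    temperature: float = 1.0
    batch_size: int = 48

    def __post_init__(self) -> None:
        if self.window_tokens <= 0:
            raise ValueError("window_tokens must be positive")
        if not (0 <= self.overlap_tokens < self.window_tokens):
            raise ValueError("overlap_tokens must satisfy 0 <= overlap < window")
        if self.decode_mode != "greedy":
            raise ValueError("only greedy decoding is supported")


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int


@dataclass(frozen=True)
class Chunk:
    note_id: str
    index: int
    token_start: int
    token_end: int
    text: str


@dataclass(frozen=True)
class BackendResponse:
    generated_text: str
    backend_id: str


@dataclass(frozen=True)
class CallContext:
    """Everything a backend may use besides the rendered prompt."""

    note_id: str
    concept_id: str
    chunk: Chunk
    prompt_index: int
    answer_mode: str


@dataclass(frozen=True)
class ChunkOutcome:
    chunk_index: int
    prompt_index: int
    raw_response: str
    outcome: str  # positive/negative/unparseable for binary; segment text or "" for measurement


@dataclass(frozen=True)
class ConceptCall:
    """Aggregated note-level decision for one (note, concept), with provenance."""

    note_id: str
    concept_id: str
    label: bool | None = None
    segments: frozenset[str] | None = None
    per_chunk: tuple[ChunkOutcome, ...] = ()

    def to_json(self) -> dict:
        d: dict = {"note_id": self.note_id, "concept_id": self.concept_id}
        if self.label is not None:
            d["label"] = self.label
        if self.segments is not None:
            d["segments"] = sorted(self.segments)
        d["per_chunk"] = [asdict(o) for o in self.per_chunk]
        return d

    @classmethod
    def from_json(cls, d: dict) -> "ConceptCall":
        return cls(
            note_id=d["note_id"],
            concept_id=d["concept_id"],
            label=d.get("label"),
            segments=None if d.get("segments") is None else frozenset(d["segments"]),
            per_chunk=tuple(ChunkOutcome(**o) for o in d.get("per_chunk", ())),
        )


class BackendError(RuntimeError):
    """A backend failed on a specific chunk; never silently skipped."""


class Backend(Protocol):
    backend_id: str

    def generate(self, prompt: str, context: CallContext) -> BackendResponse: ...


# ---------------------------------------------------------------------------
# tokenization and chunking
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\w+|[^\w\s]+")

Tokenizer = Callable[[str], list[Token]]


def simple_tokenizer(text: str) -> list[Token]:
    """Whitespace-plus-punctuation splitter with character offsets.

    Slicing the original text with each token's [start, end) reproduces the
    token text exactly; tokens are in document order. A model-specific
    tokenizer satisfying the same contract may be substituted.
    """
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def tokenize(text: str, scheme: Tokenizer | None = None) -> list[Token]:
    return (scheme or simple_tokenizer)(text)


def chunk_note(
    note: NoteRecord,
    config: ExtractionConfig | None = None,
    scheme: Tokenizer | None = None,
) -> list[Chunk]:
    """Split a note into token windows of ``window_tokens`` advancing by
    ``window - overlap`` tokens. The window starts cover every token; an empty
    note yields no chunks (never a single empty chunk).
    """
    config = config or ExtractionConfig()
    tokens = tokenize(note.text, scheme)
    n = len(tokens)
    if n == 0:
        return []
    step = config.window_tokens - config.overlap_tokens
    chunks: list[Chunk] = []
    start = 0
    index = 0
    while True:
        end = min(start + config.window_tokens, n)
        chunks.append(
            Chunk(
                note_id=note.note_id,
                index=index,
                token_start=start,
                token_end=end,
                text=note.text[tokens[start].start : tokens[end - 1].end],
            )
        )
        if end >= n:
            break
        start += step
        index += 1
    return chunks


# ---------------------------------------------------------------------------
# response parsing and aggregation
# ---------------------------------------------------------------------------

def parse_yes_no(response: BackendResponse) -> str:
    """Map generated text to positive / negative / unparseable.

    Case-insensitive; leading non-letter characters are stripped; anything not
    beginning with yes/no is unparseable (and counts as negative downstream).
    """
    text = re.sub(r"^[^A-Za-z]+", "", response.generated_text).lower()
    if text.startswith("yes"):
        return POSITIVE
    if text.startswith("no"):
        return NEGATIVE
    return UNPARSEABLE


def _query(backend: Backend, prompt: str, ctx: CallContext) -> BackendResponse:
    try:
        return backend.generate(prompt, ctx)
    except BackendError:
        raise
    except Exception as exc:  # hard error carrying chunk index, no silent skip
        raise BackendError(
            f"backend {getattr(backend, 'backend_id', '?')} failed on note "
            f"{ctx.note_id} chunk {ctx.chunk.index} prompt {ctx.prompt_index}: {exc}"
        ) from exc


def run_binary_concept(
    note: NoteRecord,
    concept: ConceptSpec,
    backend: Backend,
    config: ExtractionConfig | None = None,
    scheme: Tokenizer | None = None,
) -> ConceptCall:
    """Query every (chunk x prompt) pair; note label is the OR of parsed
    outcomes (unparseable counts as negative)."""
    if concept.kind != "binary":
        raise ValueError(f"{concept.concept_id} is not a binary concept")
    outcomes: list[ChunkOutcome] = []
    label = False
    for chunk in chunk_note(note, config, scheme):
        for pi, prompt in enumerate(concept.prompts):
            ctx = CallContext(note.note_id, concept.concept_id, chunk, pi, prompt.answer_mode)
            resp = _query(backend, render_prompt(prompt, chunk.text), ctx)
            parsed = parse_yes_no(resp)
            outcomes.append(ChunkOutcome(chunk.index, pi, resp.generated_text, parsed))
            if parsed == POSITIVE:
                label = True
    return ConceptCall(note.note_id, concept.concept_id, label=label, per_chunk=tuple(outcomes))


def run_extraction_concept(
    note: NoteRecord,
    concept: ConceptSpec,
    backend: Backend,
    config: ExtractionConfig | None = None,
    scheme: Tokenizer | None = None,
) -> ConceptCall:
    """Union of whitespace-trimmed segments over chunks; responses equal to the
    fallback token (case-insensitive) or empty are dropped."""
    if concept.kind != "measurement":
        raise ValueError(f"{concept.concept_id} is not a measurement concept")
    outcomes: list[ChunkOutcome] = []
    segments: set[str] = set()
    for chunk in chunk_note(note, config, scheme):
        for pi, prompt in enumerate(concept.prompts):
            ctx = CallContext(note.note_id, concept.concept_id, chunk, pi, prompt.answer_mode)
            resp = _query(backend, render_prompt(prompt, chunk.text), ctx)
            cleaned = resp.generated_text.strip()
            keep = cleaned and cleaned.lower() != FALLBACK_TOKEN
            outcomes.append(ChunkOutcome(chunk.index, pi, resp.generated_text, cleaned if keep else ""))
            if keep:
                segments.add(cleaned)
    return ConceptCall(
        note.note_id, concept.concept_id, segments=frozenset(segments), per_chunk=tuple(outcomes)
    )


def run_concept(note, concept, backend, config=None, scheme=None) -> ConceptCall:
    fn = run_binary_concept if concept.kind == "binary" else run_extraction_concept
    return fn(note, concept, backend, config, scheme)


def run_corpus(
    notes: Sequence[NoteRecord],
    registry: Registry,
    backend: Backend,
    config: ExtractionConfig | None = None,
    scheme: Tokenizer | None = None,
    concepts: Iterable[str] | None = None,
) -> list[ConceptCall]:
    """Run every registry concept (or the given subset) over every note."""
    ids = list(concepts) if concepts is not None else list(registry)
    return [
        run_concept(note, registry[cid], backend, config, scheme)
        for note in notes
        for cid in ids
    ]


# ---------------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------------

class PatternBackend:
    """Deterministic regex baseline.

    Ignores the rendered prompt text; identifies the concept from the call
    context and answers by pattern match on the chunk: yes/no for binary
    concepts, the matched value span (or the fallback token) for the
    measurement concept. Multiple measurement matches in one chunk are joined
    with "; " so that no mention is lost.
    """

    backend_id = "pattern"

    def __init__(self, registry: Registry | Iterable[ConceptSpec]):
        specs = registry.values() if isinstance(registry, Mapping) else registry
        self._compiled: dict[str, tuple[str, list[re.Pattern]]] = {}
        for spec in specs:
            if not spec.patterns:
                raise ValueError(f"concept {spec.concept_id} has no patterns")
            self._compiled[spec.concept_id] = (spec.kind, spec.compiled_patterns())

    def generate(self, prompt: str, context: CallContext) -> BackendResponse:
        try:
            kind, patterns = self._compiled[context.concept_id]
        except KeyError:
            raise BackendError(f"pattern backend has no patterns for {context.concept_id!r}")
        text = context.chunk.text
        if kind == "binary":
            hit = any(p.search(text) for p in patterns)
            return BackendResponse("yes" if hit else "no", self.backend_id)
        spans: list[str] = []
        for p in patterns:
            for m in p.finditer(text):
                spans.append((m.group(1) if m.groups() else m.group(0)).strip())
        out = "; ".join(dict.fromkeys(spans)) if spans else FALLBACK_TOKEN
        return BackendResponse(out, self.backend_id)


def pattern_backend(registry: Registry | Iterable[ConceptSpec]) -> PatternBackend:
    return PatternBackend(registry)


class MockBackend:
    """Test double that replays planted truth with seeded label noise.

    The flip decision is made once per (note_id, concept_id) from a stable
    hash of the seed, so all chunk and prompt calls for one concept on one
    note agree; under any-positive aggregation the note-level error rate then
    equals ``flip_rate`` exactly, independent of chunk count and prompt count.
    A flipped measurement call answers the fallback token.
    """

    backend_id = "mock"

    def __init__(
        self,
        truth: Mapping[tuple[str, str], object],
        flip_rate: float = 0.0,
        seed: int = 0,
    ):
        if not (0 <= flip_rate < 1):
            raise ValueError("flip_rate must be in [0, 1)")
        self._truth = dict(truth)
        self._flip_rate = flip_rate
        self._seed = seed

    def _flips(self, note_id: str, concept_id: str) -> bool:
        if self._flip_rate == 0:
            return False
        h = hashlib.sha256(f"{self._seed}|{note_id}|{concept_id}".encode()).digest()
        u = int.from_bytes(h[:8], "big") / 2**64
        return u < self._flip_rate

    def generate(self, prompt: str, context: CallContext) -> BackendResponse:
        key = (context.note_id, context.concept_id)
        if key not in self._truth:
            raise BackendError(f"mock backend has no planted outcome for {key}")
        planted = self._truth[key]
        flip = self._flips(*key)
        if context.answer_mode == "yes_no":
            value = bool(planted) ^ flip
            return BackendResponse("yes" if value else "no", self.backend_id)
        if flip or planted in (None, "", set(), frozenset()):
            return BackendResponse(FALLBACK_TOKEN, self.backend_id)
        if isinstance(planted, (set, frozenset, list, tuple)):
            planted = "; ".join(str(v) for v in sorted(planted))
        return BackendResponse(str(planted), self.backend_id)


def mock_backend(truth, flip_rate: float = 0.0, seed: int = 0) -> MockBackend:
    return MockBackend(truth, flip_rate, seed)


def generative_backend(endpoint: str, config: ExtractionConfig | None = None):
    """Adapter for a local seq2seq instruction model (e.g. an 11B Flan-T5
    checkpoint). Optional: requires the ``transformers`` and ``torch`` extras
    and is never exercised by the test suite.
    """
    config = config or ExtractionConfig()
    try:
        from transformers import AutoModelForSeq2SeqLM, AutoTokenizer  # type: ignore
    except ImportError as exc:
        raise ImportError(
            "the generative backend requires the optional model extra; "
            "install with: pip install pphkit[model]"
        ) from exc

    class GenerativeBackend:
        backend_id = f"generative:{endpoint}"

        def __init__(self) -> None:
            self._tok = AutoTokenizer.from_pretrained(endpoint)
            self._model = AutoModelForSeq2SeqLM.from_pretrained(endpoint)

        def generate(self, prompt: str, context: CallContext) -> BackendResponse:
            inputs = self._tok(prompt, return_tensors="pt")
            n_in = inputs["input_ids"].shape[1]
            limit = getattr(self._model.config, "n_positions", None) or getattr(
                self._model.config, "max_position_embeddings", 0
            )
            if limit and n_in > limit:
                raise BackendError(
                    f"prompt of {n_in} tokens exceeds model context {limit}; "
                    "chunking should prevent this"
                )
            out = self._model.generate(
                **inputs,
                do_sample=False,
                max_new_tokens=config.max_new_tokens,
                temperature=config.temperature,
            )
            text = self._tok.decode(out[0], skip_special_tokens=True)
            return BackendResponse(text, self.backend_id)

    return GenerativeBackend()


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_calls(calls: Iterable[ConceptCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(json.dumps(c.to_json()) + "\n")


def read_calls(path) -> list[ConceptCall]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(ConceptCall.from_json(json.loads(line)))
    return out
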