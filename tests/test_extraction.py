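"""Tokenization, chunking, response parsing, aggregation, backends."""

import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pphkit.corpus_io import NoteRecord
from pphkit.extraction import (
    BackendError,
    BackendResponse,
    CallContext,
    Chunk,
    ConceptCall,
    ExtractionConfig,
    chunk_note,
    generative_backend,
    mock_backend,
    parse_yes_no,
    pattern_backend,
    read_calls,
    run_binary_concept,
    run_extraction_concept,
    tokenize,
    write_calls,
)
from pphkit.registry import PLACEHOLDER, ConceptSpec, PromptTemplate


def _note(text, nid="n1"):
    return NoteRecord(nid, "p1", date(2005, 1, 1), "BWH", "final", "", text)


def _binary_concept(patterns=(r"atony",), n_prompts=1):
    return ConceptSpec(
        "uterine_atony", "Atony", "binary",
        tuple(PromptTemplate(f"q{i}? note: " + PLACEHOLDER) for i in range(n_prompts)),
        tuple(patterns),
    )


EBL_CONCEPT = ConceptSpec(
    "estimated_blood_loss", "EBL", "measurement",
    (PromptTemplate("extract. note: " + PLACEHOLDER, "extract"),),
    (r"ebl\s*:?\s*(\d+\s*(?:cc|ml)?)",),
)


class TestTokenize:
    def test_whitespace_and_punctuation_split_with_offsets(self):
        tokens = tokenize("EBL 500 cc")
        assert [t.text for t in tokens] == ["EBL", "500", "cc"]
        assert [(t.start, t.end) for t in tokens] == [(0, 3), (4, 7), (8, 10)]

    def test_empty_text(self):
        assert tokenize("") == []

    @settings(max_examples=200, deadline=None)
    @given(st.text(max_size=200))
    def test_offsets_slice_back_to_token_text(self, text):
        for t in tokenize(text):
            assert text[t.start : t.end] == t.text

    @settings(max_examples=100, deadline=None)
    @given(st.text(max_size=200))
    def test_tokens_ordered_and_disjoint(self, text):
        tokens = tokenize(text)
        for a, b in zip(tokens, tokens[1:]):
            assert a.end <= b.start


class TestChunkNote:
    def test_stated_window_overlap_gives_three_chunks(self):
        text = " ".join(f"w{i}" for i in range(1000))
        chunks = chunk_note(_note(text), ExtractionConfig(window_tokens=512, overlap_tokens=128))
        assert [c.token_start for c in chunks] == [0, 384, 768]
        assert chunks[-1].token_end == 1000

    def test_note_exactly_one_window_is_single_chunk(self):
        text = " ".join(f"w{i}" for i in range(512))
        chunks = chunk_note(_note(text), ExtractionConfig(512, 128))
        assert len(chunks) == 1
        assert (chunks[0].token_start, chunks[0].token_end) == (0, 512)

    def test_empty_note_yields_no_chunks(self):
        assert chunk_note(_note(""), ExtractionConfig(512, 128)) == []

    @pytest.mark.parametrize("window,overlap", [(512, 128), (8, 3), (5, 0)])
    def test_coverage_width_and_step_by_enumeration(self, window, overlap):
        rng = np.random.default_rng(7)
        config = ExtractionConfig(window_tokens=window, overlap_tokens=overlap)
        step = window - overlap
        for n in sorted(set(rng.integers(0, 2001, size=40).tolist()) | {0, 1, window - 1, window, window + 1}):
            note = _note(" ".join(f"w{i}" for i in range(n)))
            chunks = chunk_note(note, config)
            if n == 0:
                assert chunks == []
                continue
            covered = set()
            for i, c in enumerate(chunks):
                assert c.index == i
                assert c.token_start == i * step
                assert c.token_end - c.token_start <= window
                covered |= set(range(c.token_start, c.token_end))
            assert covered == set(range(n))
            assert chunks[-1].token_end == n

    def test_overlap_must_be_smaller_than_window(self):
        with pytest.raises(ValueError):
            ExtractionConfig(window_tokens=8, overlap_tokens=8)


class TestParseYesNo:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Yes", "positive"),
            ("yes, it does", "positive"),
            (" no.", "negative"),
            ("NO", "negative"),
            ('"Yes"', "positive"),
            ("maybe", "unparseable"),
            ("", "unparseable"),
            ("123", "unparseable"),
        ],
    )
    def test_parsing(self, text, expected):
        assert parse_yes_no(BackendResponse(text, "t")) == expected


class TestAggregation:
    def test_any_positive_chunk_makes_note_positive(self):
        # atony phrase in the final chunk only
        text = " ".join(f"w{i}" for i in range(20)) + " uterine atony"
        call = run_binary_concept(_note(text), _binary_concept(), pattern_backend([_binary_concept()]),
                                  ExtractionConfig(8, 3))
        assert call.label is True
        outcomes = [o.outcome for o in call.per_chunk]
        assert "positive" in outcomes and "negative" in outcomes

    def test_all_chunks_negative_across_prompts_is_negative(self):
        concept = _binary_concept(n_prompts=3)
        text = " ".join(f"w{i}" for i in range(20))
        call = run_binary_concept(_note(text), concept, pattern_backend([concept]), ExtractionConfig(8, 3))
        assert call.label is False
        assert len(call.per_chunk) == 3 * len(chunk_note(_note(text), ExtractionConfig(8, 3)))

    def test_any_prompt_positive_makes_note_positive(self):
        """With per-prompt planted outcomes, a single positive prompt suffices."""
        concept = _binary_concept(n_prompts=3)

        class PerPromptBackend:
            backend_id = "per-prompt"

            def generate(self, prompt, ctx):
                return BackendResponse("yes" if ctx.prompt_index == 2 else "no", self.backend_id)

        call = run_binary_concept(_note("some text"), concept, PerPromptBackend())
        assert call.label is True

    def test_label_equals_brute_force_or_over_chunk_outcomes(self):
        rng = np.random.default_rng(5)
        concept = _binary_concept(patterns=(r"trigger",), n_prompts=2)
        backend = pattern_backend([concept])
        config = ExtractionConfig(8, 3)
        for _ in range(30):
            n = int(rng.integers(1, 60))
            words = [f"w{i}" for i in range(n)]
            if rng.random() < 0.6:
                words[int(rng.integers(0, n))] = "trigger"
            note = _note(" ".join(words))
            call = run_binary_concept(note, concept, backend, config)
            brute = any(o.outcome == "positive" for o in call.per_chunk)
            assert call.label == brute

    def test_backend_failure_carries_chunk_index(self):
        class Exploding:
            backend_id = "boom"

            def generate(self, prompt, ctx):
                raise RuntimeError("kaput")

        with pytest.raises(BackendError, match="chunk 0"):
            run_binary_concept(_note("some text"), _binary_concept(), Exploding())


class TestExtractionAggregation:
    def test_union_drops_fallback_and_duplicates(self):
        responses = iter(["800 cc", "unanswerable", "800 cc"])

        class Scripted:
            backend_id = "scripted"

            def generate(self, prompt, ctx):
                return BackendResponse(next(responses), self.backend_id)

        text = " ".join(f"w{i}" for i in range(15))  # 3 chunks at window 8 / overlap 3
        call = run_extraction_concept(_note(text), EBL_CONCEPT, Scripted(), ExtractionConfig(8, 3))
        assert call.segments == frozenset({"800 cc"})

    def test_all_unanswerable_gives_empty_set(self):
        class Unanswerable:
            backend_id = "u"

            def generate(self, prompt, ctx):
                return BackendResponse("Unanswerable", self.backend_id)

        call = run_extraction_concept(_note("words here"), EBL_CONCEPT, Unanswerable())
        assert call.segments == frozenset()

    def test_distinct_segments_are_unioned(self):
        responses = iter(["1.5 L", "800"])

        class Scripted:
            backend_id = "s"

            def generate(self, prompt, ctx):
                return BackendResponse(next(responses), self.backend_id)

        text = " ".join(f"w{i}" for i in range(10))  # 2 chunks at window 8 / overlap 3
        call = run_extraction_concept(_note(text), EBL_CONCEPT, Scripted(), ExtractionConfig(8, 3))
        assert call.segments == frozenset({"1.5 L", "800"})


class TestPatternBackend:
    def test_binary_yes_no(self):
        concept = _binary_concept()
        backend = pattern_backend([concept])
        chunk = Chunk("n1", 0, 0, 4, "pt with uterine atony")
        ctx = CallContext("n1", "uterine_atony", chunk, 0, "yes_no")
        assert backend.generate("ignored", ctx).generated_text == "yes"
        chunk2 = Chunk("n1", 0, 0, 2, "normal delivery")
        ctx2 = CallContext("n1", "uterine_atony", chunk2, 0, "yes_no")
        assert backend.generate("ignored", ctx2).generated_text == "no"

    def test_measurement_returns_captured_span(self):
        backend = pattern_backend([EBL_CONCEPT])
        chunk = Chunk("n1", 0, 0, 3, "EBL: 800cc noted")
        ctx = CallContext("n1", "estimated_blood_loss", chunk, 0, "extract")
        assert backend.generate("ignored", ctx).generated_text == "800cc"

    def test_concept_without_patterns_rejected_at_construction(self):
        bare = ConceptSpec("x", "X", "binary", (PromptTemplate("q " + PLACEHOLDER),), ())
        with pytest.raises(ValueError, match="no patterns"):
            pattern_backend([bare])

    def test_position_invariance_across_chunk_boundaries(self):
        """A phrase shorter than the overlap is always fully inside some chunk."""
        concept = _binary_concept(patterns=(r"uterine atony",))
        backend = pattern_backend([concept])
        config = ExtractionConfig(window_tokens=8, overlap_tokens=3)
        for offset in range(0, 29):
            words = [f"w{i}" for i in range(30)]
            words[offset : offset + 2] = ["uterine", "atony"]
            call = run_binary_concept(_note(" ".join(words)), concept, backend, config)
            assert call.label is True, f"missed phrase at token offset {offset}"


class TestMockBackend:
    def _call(self, backend, nid, cid="uterine_atony", mode="yes_no"):
        chunk = Chunk(nid, 0, 0, 1, "text")
        return backend.generate("p", CallContext(nid, cid, chunk, 0, mode)).generated_text

    def test_zero_flip_rate_replays_truth(self):
        truth = {(f"n{i}", "uterine_atony"): i % 2 == 0 for i in range(50)}
        backend = mock_backend(truth, flip_rate=0.0, seed=1)
        for (nid, cid), val in truth.items():
            assert self._call(backend, nid) == ("yes" if val else "no")

    def test_flip_fraction_within_three_binomial_sd(self):
        n, rate = 1000, 0.2
        truth = {(f"n{i}", "uterine_atony"): True for i in range(n)}
        backend = mock_backend(truth, flip_rate=rate, seed=3)
        flips = sum(self._call(backend, f"n{i}") == "no" for i in range(n))
        sd = math.sqrt(n * rate * (1 - rate))
        assert abs(flips - n * rate) <= 3 * sd

    def test_same_seed_gives_identical_outcomes(self):
        truth = {(f"n{i}", "uterine_atony"): True for i in range(200)}
        a = mock_backend(truth, flip_rate=0.3, seed=9)
        b = mock_backend(truth, flip_rate=0.3, seed=9)
        assert [self._call(a, f"n{i}") for i in range(200)] == [
            self._call(b, f"n{i}") for i in range(200)
        ]

    def test_flip_consistent_across_chunks_and_prompts(self):
        backend = mock_backend({("n1", "uterine_atony"): True}, flip_rate=0.5, seed=4)
        answers = {
            backend.generate(
                "p", CallContext("n1", "uterine_atony", Chunk("n1", ci, 0, 1, "t"), pi, "yes_no")
            ).generated_text
            for ci in range(5)
            for pi in range(3)
        }
        assert len(answers) == 1

    def test_unknown_key_is_error(self):
        backend = mock_backend({("n1", "uterine_atony"): True})
        with pytest.raises(BackendError):
            self._call(backend, "unknown-note")

    def test_invalid_flip_rate(self):
        with pytest.raises(ValueError):
            mock_backend({}, flip_rate=1.0)


def test_generative_backend_absent_adapter_gives_install_hint():
    with pytest.raises(ImportError, match="pphkit\\[model\\]"):
        generative_backend("some-checkpoint")


def test_concept_call_jsonl_roundtrip(tmp_path, clean_corpus_small):
    *_, calls = clean_corpus_small
    p = tmp_path / "calls.jsonl"
    write_calls(calls[:200], p)
    assert read_calls(p) == calls[:200]
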