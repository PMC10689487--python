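import pytest

from pphkit.extraction import pattern_backend, run_corpus
from pphkit.registry import builtin_registry
from pphkit.synthgen import SynthConfig, generate


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def clean_corpus_small(registry):
    """120-delivery clean corpus with pattern-backend calls, shared across tests."""
    notes, truth, gold = generate(SynthConfig(n_notes=120, seed=11))
    calls = run_corpus(notes, registry, pattern_backend(registry))
    return notes, truth, gold, calls
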