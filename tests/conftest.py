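from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from causepattern.records import Span, SentencePairRecord, Token

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def worked_examples_dir() -> Path:
    return DATA_DIR / "worked_examples"


def make_pair(
    rec_id: str,
    cause_words,
    effect_words,
    label: str = "causality",
    pos: str = "noun",
) -> SentencePairRecord:
    """Shorthand for building a record from bare word lists (all one POS)."""
    return SentencePairRecord(
        id=rec_id,
        cause=Span(tuple(Token(w, pos) for w in cause_words), "cause"),
        effect=Span(tuple(Token(w, pos) for w in effect_words), "effect"),
        label=label,
    )


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark, generated once per session."""
    from causepattern.synthetic_data import default_benchmark

    return default_benchmark(seed=13)
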