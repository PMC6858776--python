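from __future__ import annotations

import pytest

from clinum.lexicon import build_lexicon, load_specs
from clinum.pipeline import Extractor
from clinum.preprocessing import Token


@pytest.fixture(scope="session")
def default_specs():
    return load_specs()

@pytest.fixture(scope="session")
def specs_by_name(default_specs):
    return {s.name: s for s in default_specs}


@pytest.fixture(scope="session")
def lexicon(default_specs):
    return build_lexicon(default_specs)


@pytest.fixture(scope="session")
def extractor():
    return Extractor()


def make_tokens(words: list[str], sentence_index: int = 0) -> list[Token]:
    """Build a token list with consistent synthetic offsets."""
    tokens = []
    pos = 0
    for word in words:
        tokens.append(
            Token(surface=word, start=pos, end=pos + len(word),
                  sentence_index=sentence_index)
        )
        pos += len(word) + 1
    return tokens
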