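"""Note normalization, sentence segmentation and tokenization.

Normalization is length-preserving: every removed character is replaced by a
single space, so a character offset into the normalized text is also an
offset into the raw text (the offset map is the identity).  This keeps token
spans valid against the source document without any bookkeeping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "RawNote",
    "Token",
    "TokenizedNote",
    "normalize",
    "split_sentences",
    "tokenize_sentence",
    "filter_stopwords",
    "preprocess",
    "canon",
    "default_stopwords",
]

#: characters that carry numeric or relational meaning and must survive
#: normalization untouched.
_PRESERVED = frozenset(".%/-<>:")

#: unicode dash variants folded to an ASCII hyphen.
_DASHES = frozenset({"–", "—", "−"})


@dataclass(frozen=True)
class RawNote:
    """A raw clinical note: opaque id plus free text."""

    note_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.note_id:
            raise ValueError("note_id must be non-empty")


@dataclass(frozen=True)
class Token:
    """One word-level token with half-open character offsets into the raw text."""

    surface: str
    start: int
    end: int
    sentence_index: int


@dataclass
class TokenizedNote:
    note_id: str
    raw_text: str
    normalized: str
    sentences: list[list[Token]] = field(default_factory=list)


def normalize(text: str) -> str:
    """Lowercase ``text`` and blank out grammatical punctuation.

    Digits, letters and the characters ``. / % - < > :`` are kept; unicode
    dashes become ``-`` and ``≤``/``≥`` degrade to ``<``/``>``.  Everything
    else (commas, quotes, parentheses, ...) is replaced by a single space.
    The result has exactly the same length as the input.
    """
    out = []
    for ch in text:
        if ch in _DASHES:
            out.append("-")
        elif ch == "≤":
            out.append("<")
        elif ch == "≥":
            out.append(">")
        elif ch == "\n":
            out.append("\n")
        elif ch.isspace():
            out.append(" ")
        elif ch.isalnum():
            low = ch.lower()
            out.append(low if len(low) == 1 else ch)
        elif ch in _PRESERVED:
            out.append(ch)
        else:
            out.append(" ")
    return "".join(out)


def _is_boundary_period(text: str, i: int, abbreviations: frozenset[str]) -> bool:
    """True when ``text[i] == '.'`` terminates a sentence.

    A period ends a sentence only when followed by whitespace whose next
    non-space character is a letter.  This never fires inside a decimal
    (``101.2``) and keeps abbreviation-value pairs such as ``resp. 18``
    in one sentence.  A period closing a known abbreviation (``resp.`` when
    the respiratory-rate dictionary is active) never ends a sentence either.
    """
    if text[i] != ".":
        return False
    j = i + 1
    if j < len(text) and not text[j].isspace():
        return False
    while j < len(text) and text[j] in " \n":
        j += 1
    if not (j < len(text) and text[j].isalpha()):
        return False
    if abbreviations:
        k = i
        while k > 0 and (text[k - 1].isalnum() or text[k - 1] in "./-"):
            k -= 1
        if text[k : i + 1] in abbreviations:
            return False
    return True


def split_sentences(
    normalized: str, abbreviations: frozenset[str] = frozenset()
) -> list[tuple[int, int]]:
    """Return half-open ``(start, end)`` spans of sentences in ``normalized``.

    Boundaries fall after sentence-terminating periods and at newlines.
    ``abbreviations`` holds period-bearing word forms (``resp.``) whose
    period never ends a sentence.  Spans containing only whitespace are
    dropped.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for i, ch in enumerate(normalized):
        if ch == "\n" or _is_boundary_period(normalized, i, abbreviations):
            end = i + 1 if ch != "\n" else i
            if normalized[start:end].strip():
                spans.append((start, end))
            start = i + 1
    if normalized[start:].strip():
        spans.append((start, len(normalized)))
    return spans


_TOKEN_RE = re.compile(r"[^\s:]+|:")


def tokenize_sentence(
    normalized: str, span: tuple[int, int], sentence_index: int
) -> list[Token]:
    """Tokenize one sentence span on whitespace, splitting ``:`` off as its
    own token (so ``bp: 132/78`` yields ``bp``, ``:``, ``132/78``)."""
    start, end = span
    tokens = []
    for m in _TOKEN_RE.finditer(normalized, start, end):
        tokens.append(
            Token(
                surface=m.group(),
                start=m.start(),
                end=m.end(),
                sentence_index=sentence_index,
            )
        )
    return tokens


def canon(surface: str) -> str:
    """Canonical lookup form of a token: trailing sentence periods stripped
    (``99.1.`` → ``99.1``, ``resp.`` → ``resp``) unless that empties it."""
    stripped = surface.rstrip(".")
    return stripped if stripped else surface


def filter_stopwords(
    tokens: list[Token],
    stopword_set: frozenset[str] | set[str],
    protected_terms: frozenset[str] | set[str] = frozenset(),
) -> list[Token]:
    """Drop stop-word tokens unless they appear in any variable dictionary.

    ``protected_terms`` should contain every individual word of every active
    dictionary term (so multi-word terms survive intact).  Offsets of the
    surviving tokens are untouched.
    """
    return [
        t
        for t in tokens
        if canon(t.surface) not in stopword_set or canon(t.surface) in protected_terms
    ]


def default_stopwords() -> frozenset[str]:
    """The stop-word list shipped with the package."""
    text = (
        resources.files("clinum.data").joinpath("stopwords.txt").read_text("utf-8")
    )
    words = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


def preprocess(
    note: RawNote,
    stopwords: frozenset[str] | None = None,
    protected_terms: frozenset[str] | set[str] = frozenset(),
    abbreviations: frozenset[str] = frozenset(),
) -> TokenizedNote:
    """Full preprocessing: normalize, segment, tokenize, filter stop words."""
    if stopwords is None:
        stopwords = default_stopwords()
    normalized = normalize(note.text)
    sentences = []
    for idx, span in enumerate(split_sentences(normalized, abbreviations)):
        tokens = tokenize_sentence(normalized, span, idx)
        tokens = filter_stopwords(tokens, stopwords, protected_terms)
        if tokens:
            sentences.append(tokens)
    return TokenizedNote(
        note_id=note.note_id,
        raw_text=note.text,
        normalized=normalized,
        sentences=sentences,
    )
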