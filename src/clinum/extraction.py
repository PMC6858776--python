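"""Candidate extraction: term-adjacent values and unlabeled number groups.

Two extraction categories are implemented:

1. term-adjacent — a dictionary term with a numeric value (or range) nearby
   in the same sentence, forward-preferred within a token window;
2. number groups — a run of three or more unlabeled numeric tokens that
   passes a set of plausibility rules and is then assigned positionally to
   the vital-sign panel (temperature, blood pressure, heart rate,
   respiratory rate, oxygen saturation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .lexicon import (
    TermHit,
    TermTrie,
    VariableSpec,
    match_terms,
    protected_term_tokens,
    term_abbreviations,
)
from .preprocessing import RawNote, Token, canon, default_stopwords, preprocess

__all__ = [
    "NumericToken",
    "Candidate",
    "NumberGroup",
    "parse_numeric",
    "format_ok",
    "extract_term_adjacent",
    "find_number_groups",
    "is_vital_group",
    "assign_group",
    "extract_note",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 5

_RE_SCALAR = re.compile(r"^(\d+(?:\.\d+)?)(%?)$")
_RE_FRACTION = re.compile(r"^(\d+(?:\.\d+)?)/(\d+(?:\.\d+)?)$")
_RE_RANGE = re.compile(r"^(\d+(?:\.\d+)?)-(\d+(?:\.\d+)?)(%?)$")

#: single-token condition symbols (after normalization ≤/≥ degrade to </>).
_CONDITION_SYMBOLS = {"<": "<", ">": ">"}
#: two-token condition phrases, keyed by (first, second) token.
_CONDITION_PHRASES = {
    ("less", "than"): "<",
    ("lower", "than"): "<",
    ("greater", "than"): ">",
    ("higher", "than"): ">",
    ("at", "least"): ">=",
    ("at", "most"): "<=",
}

#: words of the condition vocabulary; protected from stop-word removal
#: ("than" and "at" are ordinary stop words but load-bearing here).
CONDITION_WORDS = frozenset(w for pair in _CONDITION_PHRASES for w in pair)

#: explicit unit tokens and their canonical labels. "in" is deliberately
#: absent (too ambiguous with the preposition).
_UNIT_TOKENS = {
    "f": "°F",
    "fahrenheit": "°F",
    "%": "%",
    "percent": "%",
    "mg/dl": "mg/dL",
    "mmhg": "mmHg",
    "bpm": "bpm",
    "kg": "kg",
    "kgs": "kg",
    "lb": "lb",
    "lbs": "lb",
    "cm": "cm",
}


@dataclass(frozen=True)
class NumericToken:
    """A token parsed as a number, fraction, percentage or range."""

    surface: str
    value_low: float
    value_high: float
    is_fraction: bool = False
    numerator: float | None = None
    denominator: float | None = None
    has_decimal: bool = False
    has_percent: bool = False
    is_range: bool = False
    token_index: int = -1

    @property
    def is_plain_integer(self) -> bool:
        return not (
            self.is_fraction or self.is_range or self.has_decimal or self.has_percent
        )


@dataclass
class Candidate:
    """A (variable, value-or-range) pair awaiting the validity test."""

    variable: str
    value_low: float
    value_high: float
    source: str  # "term_adjacent" | "number_group"
    note_id: str = ""
    sentence_index: int = -1
    char_span: tuple[int, int] = (-1, -1)
    term: str | None = None
    condition: str | None = None  # "<", ">", "<=", ">=" or None
    is_fraction: bool = False
    numerator: float | None = None
    denominator: float | None = None
    has_decimal: bool = False
    has_percent: bool = False
    is_range: bool = False
    unit_hint: str | None = None
    #: token index of the numeric value inside its sentence (internal, used
    #: for competition resolution and group exclusion).
    value_token_index: int = -1
    #: token distance between term and value (internal tie-break key).
    term_distance: int = 0


@dataclass
class NumberGroup:
    """A maximal run of adjacent numeric tokens with no term inside."""

    numeric_tokens: list[NumericToken]
    token_indices: list[int]
    sentence_index: int
    char_span: tuple[int, int]
    #: per-member raw-text spans, parallel to ``numeric_tokens``.
    token_spans: list[tuple[int, int]] | None = None


def parse_numeric(surface: str) -> NumericToken | None:
    """Parse one token surface into a :class:`NumericToken`, or ``None``.

    Recognized shapes: ``98``, ``97.0``, ``98%``, ``98.6%``, ``100/66``,
    ``10-15`` and ``35-55%``.  A trailing sentence period is ignored.
    A descending "range" (``20-10``) is not treated as numeric.
    """
    s = canon(surface)
    m = _RE_SCALAR.match(s)
    if m:
        value = float(m.group(1))
        return NumericToken(
            surface=s,
            value_low=value,
            value_high=value,
            has_decimal="." in m.group(1),
            has_percent=bool(m.group(2)),
        )
    m = _RE_FRACTION.match(s)
    if m:
        num, den = float(m.group(1)), float(m.group(2))
        return NumericToken(
            surface=s,
            value_low=num,
            value_high=den,
            is_fraction=True,
            numerator=num,
            denominator=den,
            has_decimal="." in s,
        )
    m = _RE_RANGE.match(s)
    if m:
        low, high = float(m.group(1)), float(m.group(2))
        if low > high:
            return None
        return NumericToken(
            surface=s,
            value_low=low,
            value_high=high,
            is_range=True,
            has_decimal="." in s,
            has_percent=bool(m.group(3)),
        )
    return None


def format_ok(spec: VariableSpec, numeric: NumericToken) -> bool:
    """Does this numeric token's shape fit the variable's allowed formats?"""
    if numeric.is_fraction:
        return "fraction" in spec.formats
    if numeric.is_range:
        return "range" in spec.formats
    if numeric.has_percent:
        return "percent" in spec.formats
    if numeric.has_decimal:
        return "decimal" in spec.formats
    return "integer" in spec.formats


def _condition_at(tokens: list[Token], j: int) -> tuple[str, int] | None:
    """Condition symbol starting at token ``j`` → (symbol, tokens consumed)."""
    word = canon(tokens[j].surface)
    if j + 1 < len(tokens):
        pair = (word, canon(tokens[j + 1].surface))
        if pair in _CONDITION_PHRASES:
            return _CONDITION_PHRASES[pair], 2
    if word in _CONDITION_SYMBOLS:
        return _CONDITION_SYMBOLS[word], 1
    return None


def _scan_forward(
    tokens: list[Token],
    numerics: list[NumericToken | None],
    start: int,
    spec: VariableSpec,
    window: int,
) -> tuple[int, str | None] | None:
    condition = None
    steps = 0
    j = start
    while j < len(tokens) and steps < window:
        nt = numerics[j]
        if nt is not None and format_ok(spec, nt):
            return j, condition
        cond = _condition_at(tokens, j)
        if cond is not None:
            condition = cond[0]
            j += cond[1]
            steps += cond[1]
            continue
        j += 1
        steps += 1
    return None


def _scan_backward(
    tokens: list[Token],
    numerics: list[NumericToken | None],
    start: int,
    spec: VariableSpec,
    window: int,
) -> tuple[int, str | None] | None:
    condition = None
    steps = 0
    j = start
    while j >= 0 and steps < window:
        nt = numerics[j]
        if nt is not None and format_ok(spec, nt):
            return j, condition
        if j - 1 >= 0:
            cond = _condition_at(tokens, j - 1)
            if cond is not None and cond[1] == 2:
                condition = cond[0]
                j -= 2
                steps += 2
                continue
        cond = _condition_at(tokens, j)
        if cond is not None and cond[1] == 1:
            condition = cond[0]
        j -= 1
        steps += 1
    return None


def extract_term_adjacent(
    tokens: list[Token],
    numerics: list[NumericToken | None],
    hit: TermHit,
    spec: VariableSpec,
    window: int = DEFAULT_WINDOW,
) -> list[Candidate]:
    """Pair a term hit with its nearest valid-format numeric token.

    The forward direction is searched first, then backward, each within
    ``window`` tokens.  Inequality words or symbols crossed on the way are
    recorded as the candidate's condition, never consumed as the value.  A
    trailing ``percent``/``%`` token folds into the value, and an adjacent
    explicit unit token is kept as a hint for the validity test.
    """
    first, last = hit.token_span
    found = _scan_forward(tokens, numerics, last + 1, spec, window)
    direction = 1
    if found is None:
        found = _scan_backward(tokens, numerics, first - 1, spec, window)
        direction = -1
    if found is None:
        return []
    j, condition = found
    numeric = numerics[j]
    assert numeric is not None

    has_percent = numeric.has_percent
    unit_hint = "%" if has_percent else None
    end_span = tokens[j].end
    k = j + 1
    if k < len(tokens) and not (first <= k <= last):
        nxt = canon(tokens[k].surface)
        if nxt in ("percent", "%"):
            has_percent = True
            unit_hint = "%"
            end_span = tokens[k].end
            k += 1
    if unit_hint is None and k < len(tokens) and not (first <= k <= last):
        nxt = canon(tokens[k].surface)
        if nxt in _UNIT_TOKENS:
            unit_hint = _UNIT_TOKENS[nxt]

    distance = j - last if direction == 1 else first - j
    return [
        Candidate(
            variable=spec.name,
            value_low=numeric.value_low,
            value_high=numeric.value_high,
            source="term_adjacent",
            sentence_index=tokens[j].sentence_index,
            char_span=(tokens[j].start, end_span),
            term=hit.term,
            condition=condition,
            is_fraction=numeric.is_fraction,
            numerator=numeric.numerator,
            denominator=numeric.denominator,
            has_decimal=numeric.has_decimal,
            has_percent=has_percent,
            is_range=numeric.is_range,
            unit_hint=unit_hint,
            value_token_index=j,
            term_distance=distance * direction,
        )
    ]


def find_number_groups(
    tokens: list[Token],
    numerics: list[NumericToken | None],
    excluded_indices: set[int],
) -> list[NumberGroup]:
    """Maximal runs of ≥3 consecutive numeric tokens.

    ``excluded_indices`` carries term-token positions and numeric tokens
    already claimed by term-adjacent candidates; an excluded index breaks a
    run.  Runs of one or two numeric tokens are never groups.
    """
    groups: list[NumberGroup] = []
    run: list[int] = []

    def flush() -> None:
        if len(run) >= 3:
            members = [replace(numerics[i], token_index=i) for i in run]  # type: ignore[arg-type]
            groups.append(
                NumberGroup(
                    numeric_tokens=members,
                    token_indices=list(run),
                    sentence_index=tokens[run[0]].sentence_index,
                    char_span=(tokens[run[0]].start, tokens[run[-1]].end),
                    token_spans=[(tokens[i].start, tokens[i].end) for i in run],
                )
            )
        run.clear()

    for i in range(len(tokens)):
        if numerics[i] is not None and i not in excluded_indices:
            run.append(i)
        else:
            flush()
    flush()
    return groups


_GROUP_CHARS_RE = re.compile(r"^[0-9./%]+$")


def is_vital_group(group: NumberGroup) -> bool:
    """Plausibility rules deciding whether a number run is a vital-sign panel.

    All of the following must hold:

    1. every token is built only from digits and ``.``, ``%``, ``/``
       (a range token like ``10-15`` disqualifies the whole group);
    2. at most one fraction token, at most one percent token, and at most
       two decimal-pointed tokens in the group;
    3. every plain integer is < 300;
    4. every decimal value v satisfies 93 < v < 110 (read as a conjunction:
       a plausible-body-temperature filter).
    """
    n_fraction = n_percent = n_decimal = 0
    for nt in group.numeric_tokens:
        if not _GROUP_CHARS_RE.match(nt.surface):
            return False
        if nt.is_fraction:
            n_fraction += 1
        if nt.has_percent:
            n_percent += 1
        if "." in nt.surface:
            n_decimal += 1
        if nt.is_plain_integer and nt.value_low >= 300:
            return False
        if nt.has_decimal and not nt.is_fraction:
            if not (93 < nt.value_low < 110):
                return False
    return n_fraction <= 1 and n_percent <= 1 and n_decimal <= 2


def assign_group(
    group: NumberGroup, specs: dict[str, VariableSpec]
) -> list[Candidate]:
    """Assign a validated group's tokens to vital-sign variables.

    Single left-to-right pass over signature-bearing tokens: a decimal in
    the temperature window fills temperature, a fraction whose components
    sit in the systolic/diastolic windows fills blood pressure, a percent
    token fills oxygen saturation.  Remaining plain integers then fill
    heart rate, respiratory rate and (if still empty) oxygen saturation in
    panel order, each gated by that variable's viable range.  Every
    variable is filled at most once; unmatched tokens stay unassigned.
    """
    filled: dict[str, NumericToken] = {}

    t_spec = specs.get("temperature")
    bp_spec = specs.get("blood_pressure")
    hr_spec = specs.get("heart_rate")
    rr_spec = specs.get("respiratory_rate")
    o2_spec = specs.get("o2_saturation")

    integers: list[NumericToken] = []
    for nt in group.numeric_tokens:
        if (
            t_spec is not None
            and t_spec.group_eligible
            and "temperature" not in filled
            and nt.has_decimal
            and not nt.is_fraction
            and not nt.has_percent
            and 93 < nt.value_low < 110
        ):
            filled["temperature"] = nt
        elif (
            bp_spec is not None
            and bp_spec.group_eligible
            and "blood_pressure" not in filled
            and nt.is_fraction
            and _in_range(nt.numerator, bp_spec.viable_range)
            and _in_range(nt.denominator, bp_spec.secondary_range or bp_spec.viable_range)
        ):
            filled["blood_pressure"] = nt
        elif (
            o2_spec is not None
            and o2_spec.group_eligible
            and "o2_saturation" not in filled
            and nt.has_percent
            and not nt.is_fraction
        ):
            filled["o2_saturation"] = nt
        elif nt.is_plain_integer:
            integers.append(nt)

    positional = [
        ("heart_rate", hr_spec),
        ("respiratory_rate", rr_spec),
        ("o2_saturation", o2_spec),
    ]
    for nt in integers:
        for name, spec in positional:
            if spec is None or not spec.group_eligible or name in filled:
                continue
            if _in_range(nt.value_low, spec.viable_range):
                filled[name] = nt
                break

    candidates = []
    order = {idx: pos for pos, idx in enumerate(group.token_indices)}
    for name, nt in sorted(filled.items(), key=lambda kv: order[kv[1].token_index]):
        candidates.append(
            Candidate(
                variable=name,
                value_low=nt.value_low,
                value_high=nt.value_high,
                source="number_group",
                sentence_index=group.sentence_index,
                char_span=_token_char_span(group, nt),
                term=None,
                is_fraction=nt.is_fraction,
                numerator=nt.numerator,
                denominator=nt.denominator,
                has_decimal=nt.has_decimal,
                has_percent=nt.has_percent,
                is_range=nt.is_range,
                unit_hint="%" if nt.has_percent else None,
                value_token_index=nt.token_index,
            )
        )
    return candidates


def _in_range(value: float | None, bounds: tuple[float, float]) -> bool:
    return value is not None and bounds[0] <= value <= bounds[1]


def _token_char_span(group: NumberGroup, nt: NumericToken) -> tuple[int, int]:
    if group.token_spans is None:
        return group.char_span
    return group.token_spans[group.token_indices.index(nt.token_index)]


def _resolve_competition(candidates: list[Candidate]) -> list[Candidate]:
    """When several terms claim one numeric token, the nearest term wins;
    on an exact distance tie, the term that precedes the value wins."""
    by_token: dict[tuple[int, int], list[Candidate]] = {}
    for cand in candidates:
        key = (cand.sentence_index, cand.value_token_index)
        by_token.setdefault(key, []).append(cand)
    kept = []
    for group in by_token.values():
        group.sort(key=lambda c: (abs(c.term_distance), 0 if c.term_distance > 0 else 1))
        kept.append(group[0])
    return kept


def extract_note(
    note: RawNote,
    lexicon: TermTrie,
    specs: dict[str, VariableSpec] | list[VariableSpec],
    window: int = DEFAULT_WINDOW,
    stopwords: frozenset[str] | None = None,
) -> list[Candidate]:
    """Run the full extraction pass over one note and return all candidates.

    Orchestrates preprocessing → term matching → term-adjacent extraction →
    number-group detection and assignment.  Numeric tokens consumed by a
    term-adjacent candidate are excluded from groups, and duplicates of the
    same (variable, value) at overlapping spans keep the term-adjacent one.
    """
    if isinstance(specs, list):
        specs = {s.name: s for s in specs}
    if stopwords is None:
        stopwords = default_stopwords()
    protected = protected_term_tokens(specs.values()) | CONDITION_WORDS
    tokenized = preprocess(
        note,
        stopwords=stopwords,
        protected_terms=protected,
        abbreviations=term_abbreviations(specs.values()),
    )

    all_candidates: list[Candidate] = []
    for tokens in tokenized.sentences:
        numerics = [parse_numeric(t.surface) for t in tokens]
        hits = match_terms(tokens, lexicon)

        term_adjacent: list[Candidate] = []
        term_indices: set[int] = set()
        for hit in hits:
            term_indices.update(range(hit.token_span[0], hit.token_span[1] + 1))
            spec = specs.get(hit.variable)
            if spec is None:
                continue
            term_adjacent.extend(
                extract_term_adjacent(tokens, numerics, hit, spec, window)
            )
        term_adjacent = _resolve_competition(term_adjacent)

        claimed = {c.value_token_index for c in term_adjacent}
        excluded = term_indices | claimed
        group_candidates: list[Candidate] = []
        for group in find_number_groups(tokens, numerics, excluded):
            if is_vital_group(group):
                group_candidates.extend(assign_group(group, specs))

        seen = {(c.variable, c.value_low, c.value_high) for c in term_adjacent}
        for cand in group_candidates:
            key = (cand.variable, cand.value_low, cand.value_high)
            if key in seen and any(
                c.variable == cand.variable
                and _spans_overlap(c.char_span, cand.char_span)
                for c in term_adjacent
            ):
                continue
            term_adjacent.append(cand)
        all_candidates.extend(term_adjacent)

    for cand in all_candidates:
        cand.note_id = note.note_id
    all_candidates.sort(key=lambda c: c.char_span)
    return all_candidates


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]
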