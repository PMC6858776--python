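"""Per-variable term dictionaries and prefix-tree term matching.

The shipped defaults live in ``data/default_variables.yaml`` and mirror the
published dictionary verbatim.  Matching operates on whole tokens only; a
multi-word term is stored as a token sequence in the trie and the longest
match at each position wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable

import yaml

from .preprocessing import Token, canon

__all__ = [
    "VariableSpec",
    "TermHit",
    "ConfigError",
    "VARIABLE_NAMES",
    "load_specs",
    "build_lexicon",
    "match_terms",
    "protected_term_tokens",
    "TermTrie",
]

VARIABLE_NAMES = (
    "temperature",
    "blood_pressure",
    "respiratory_rate",
    "heart_rate",
    "o2_saturation",
    "ejection_fraction",
    "hba1c",
    "creatinine",
    "height",
    "weight",
)

_ALLOWED_FORMATS = {"integer", "decimal", "fraction", "percent", "range"}
_ALLOWED_POLICIES = {"reject_conditions", "accept_conditions"}


class ConfigError(ValueError):
    """Raised on a malformed variable configuration; names the bad field."""


@dataclass
class VariableSpec:
    """Everything the pipeline knows about one clinical parameter."""

    name: str
    terms: list[str]
    viable_range: tuple[float, float]
    formats: frozenset[str]
    condition_policy: str
    unit: str
    group_eligible: bool = False
    #: second numeric component's range (diastolic bound for blood pressure).
    secondary_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.terms:
            raise ConfigError(f"{self.name}.terms: must be non-empty")
        self.terms = [str(t).lower() for t in self.terms]
        lo, hi = self.viable_range
        if not lo < hi:
            raise ConfigError(
                f"{self.name}.viable_range: low must be < high, got [{lo}, {hi}]"
            )
        self.viable_range = (float(lo), float(hi))
        if self.secondary_range is not None:
            slo, shi = self.secondary_range
            if not slo < shi:
                raise ConfigError(
                    f"{self.name}.secondary_range: low must be < high, "
                    f"got [{slo}, {shi}]"
                )
            self.secondary_range = (float(slo), float(shi))
        bad = set(self.formats) - _ALLOWED_FORMATS
        if bad:
            raise ConfigError(f"{self.name}.formats: unknown format(s) {sorted(bad)}")
        self.formats = frozenset(self.formats)
        if self.condition_policy not in _ALLOWED_POLICIES:
            raise ConfigError(
                f"{self.name}.condition_policy: must be one of "
                f"{sorted(_ALLOWED_POLICIES)}, got {self.condition_policy!r}"
            )


@dataclass(frozen=True)
class TermHit:
    """A dictionary term matched over a run of whole tokens."""

    variable: str
    term: str
    token_span: tuple[int, int]  # [first_token_index, last_token_index], inclusive
    char_span: tuple[int, int]  # raw-text offsets, half-open


def _default_config() -> dict[str, Any]:
    text = (
        resources.files("clinum.data")
        .joinpath("default_variables.yaml")
        .read_text("utf-8")
    )
    return yaml.safe_load(text)


def _spec_from_block(name: str, block: dict[str, Any]) -> VariableSpec:
    if not isinstance(block, dict):
        raise ConfigError(f"{name}: expected a mapping, got {type(block).__name__}")
    unknown = set(block) - {
        "terms",
        "viable_range",
        "secondary_range",
        "formats",
        "condition_policy",
        "unit",
        "group_eligible",
    }
    if unknown:
        raise ConfigError(f"{name}: unknown field(s) {sorted(unknown)}")
    try:
        viable = tuple(block["viable_range"])
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{name}.viable_range: missing or malformed") from exc
    if len(viable) != 2:
        raise ConfigError(f"{name}.viable_range: expected [low, high]")
    secondary = block.get("secondary_range")
    if secondary is not None:
        secondary = tuple(secondary)
        if len(secondary) != 2:
            raise ConfigError(f"{name}.secondary_range: expected [low, high]")
    return VariableSpec(
        name=name,
        terms=list(block.get("terms", [])),
        viable_range=viable,  # type: ignore[arg-type]
        formats=frozenset(block.get("formats", [])),
        condition_policy=block.get("condition_policy", "reject_conditions"),
        unit=str(block.get("unit", "")),
        group_eligible=bool(block.get("group_eligible", False)),
        secondary_range=secondary,  # type: ignore[arg-type]
    )


def load_specs(config: str | dict[str, Any] | None = None) -> list[VariableSpec]:
    """Load variable specifications.

    ``config`` may be ``None`` (ship the defaults), a path to a YAML/JSON
    file, or an already-parsed mapping.  A user config overrides or extends
    the default blocks field-by-field: supplying only ``terms`` for
    ``temperature`` keeps the default range and policies.
    """
    merged = _default_config()
    if config is not None:
        if isinstance(config, (str, bytes)):
            with open(config, "r", encoding="utf-8") as fh:
                user = yaml.safe_load(fh)
        else:
            user = config
        if not isinstance(user, dict):
            raise ConfigError("config root: expected a mapping of variable blocks")
        for name, block in user.items():
            if not isinstance(block, dict):
                raise ConfigError(f"{name}: expected a mapping")
            base = dict(merged.get(name, {}))
            base.update(block)
            merged[name] = base

    specs = [_spec_from_block(name, block) for name, block in merged.items()]

    seen: dict[str, str] = {}
    for spec in specs:
        for term in spec.terms:
            if term in seen and seen[term] != spec.name:
                warnings.warn(
                    f"term {term!r} is shared by {seen[term]!r} and "
                    f"{spec.name!r}; both kept, validity checks disambiguate",
                    stacklevel=2,
                )
            seen.setdefault(term, spec.name)
    return specs


class TermTrie:
    """Token-level prefix tree over multi-word terms."""

    _TERMINAL = None  # sentinel key for "a term ends here"

    def __init__(self) -> None:
        self._root: dict = {}
        self._size = 0

    def insert(self, term: str, variable: str) -> None:
        node = self._root
        for word in term.split():
            node = node.setdefault(canon(word), {})
        node.setdefault(self._TERMINAL, []).append((variable, term))
        self._size += 1

    def lookup(self, term: str) -> list[tuple[str, str]]:
        """Exact lookup of a (possibly multi-word) term string."""
        node = self._root
        for word in term.split():
            node = node.get(canon(word))
            if node is None:
                return []
        return list(node.get(self._TERMINAL, []))

    def longest_match(
        self, tokens: list[Token], start: int
    ) -> tuple[int, list[tuple[str, str]]] | None:
        """Longest term starting at token ``start``.

        Returns ``(last_index, [(variable, term), ...])`` or ``None``.
        """
        node = self._root
        best: tuple[int, list[tuple[str, str]]] | None = None
        i = start
        while i < len(tokens):
            node = node.get(canon(tokens[i].surface))
            if node is None:
                break
            if self._TERMINAL in node:
                best = (i, node[self._TERMINAL])
            i += 1
        return best

    def __len__(self) -> int:
        return self._size


def build_lexicon(specs: Iterable[VariableSpec]) -> TermTrie:
    """Index every term of every spec into one shared trie."""
    trie = TermTrie()
    for spec in specs:
        for term in spec.terms:
            trie.insert(term, spec.name)
    return trie


def match_terms(tokens: list[Token], lexicon: TermTrie) -> list[TermHit]:
    """Match dictionary terms over whole tokens, longest match first.

    Matches never overlap: after a hit the scan resumes past its last token.
    A term shared by several variables yields one hit per variable at the
    same span.
    """
    hits: list[TermHit] = []
    i = 0
    while i < len(tokens):
        found = lexicon.longest_match(tokens, i)
        if found is None:
            i += 1
            continue
        last, entries = found
        for variable, term in entries:
            hits.append(
                TermHit(
                    variable=variable,
                    term=term,
                    token_span=(i, last),
                    char_span=(tokens[i].start, tokens[last].end),
                )
            )
        i = last + 1
    return hits


def protected_term_tokens(specs: Iterable[VariableSpec]) -> frozenset[str]:
    """Every individual word of every term — the stop-word protection set."""
    words: set[str] = set()
    for spec in specs:
        for term in spec.terms:
            words.update(canon(w) for w in term.split())
    return frozenset(words)


def term_abbreviations(specs: Iterable[VariableSpec]) -> frozenset[str]:
    """Term words that carry their own period (``resp.``, ``ht.``); the
    sentence splitter must not treat these periods as boundaries."""
    words: set[str] = set()
    for spec in specs:
        for term in spec.terms:
            words.update(w for w in term.split() if w.endswith("."))
    return frozenset(words)
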