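"""End-to-end pipeline: preprocessing → term matching → extraction → validity."""

from __future__ import annotations

from typing import Iterable

from .extraction import DEFAULT_WINDOW, Candidate, extract_note
from .lexicon import VariableSpec, build_lexicon, load_specs
from .preprocessing import RawNote, default_stopwords
from .validity import Annotation, ValidityResult, finalize

__all__ = ["Extractor"]


class Extractor:
    """Reusable extraction pipeline bound to a set of variable specs.

    Parameters
    ----------
    specs:
        Variable specifications; ``None`` loads the shipped defaults.
    window:
        Token window for term-adjacent value search.
    variables:
        Optional subset of variable names to extract; others are ignored.
    """

    def __init__(
        self,
        specs: list[VariableSpec] | None = None,
        window: int = DEFAULT_WINDOW,
        variables: Iterable[str] | None = None,
        stopwords: frozenset[str] | None = None,
    ) -> None:
        if specs is None:
            specs = load_specs()
        if variables is not None:
            wanted = set(variables)
            unknown = wanted - {s.name for s in specs}
            if unknown:
                raise ValueError(f"unknown variable(s): {sorted(unknown)}")
            specs = [s for s in specs if s.name in wanted]
        self.specs = {s.name: s for s in specs}
        self.lexicon = build_lexicon(specs)
        self.window = window
        self.stopwords = stopwords if stopwords is not None else default_stopwords()

    def candidates(self, note: RawNote) -> list[Candidate]:
        """Extraction only — no validity filtering."""
        return extract_note(
            note, self.lexicon, self.specs, window=self.window, stopwords=self.stopwords
        )

    def annotate(
        self, note: RawNote
    ) -> tuple[list[Annotation], list[tuple[Candidate, ValidityResult]]]:
        """Extract and validity-filter one note."""
        return finalize(self.candidates(note), self.specs)

    def annotate_corpus(
        self, notes: Iterable[RawNote]
    ) -> tuple[list[Annotation], list[tuple[Candidate, ValidityResult]]]:
        annotations: list[Annotation] = []
        rejects: list[tuple[Candidate, ValidityResult]] = []
        for note in notes:
            acc, rej = self.annotate(note)
            annotations.extend(acc)
            rejects.extend(rej)
        return annotations, rejects
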