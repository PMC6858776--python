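"""Synthetic clinical-note generator with known gold annotations.

Emulates the two documentation styles the extractor targets — labeled
term–value pairs ("bp 132/78", "fever, 101.2") and unlabeled vital-sign
panels ("97.0 100/66 98 18 98%") — plus negative distractors: condition
expressions ("fever > 100.4"), pseudo-table number runs that violate the
group rules, term-only mentions and term-free text.  Every note carries its
gold annotations, so the whole pipeline is testable without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import GoldAnnotation
from .preprocessing import RawNote

__all__ = ["GeneratorConfig", "SyntheticCorpus", "generate_corpus", "plant_confusion"]

TEMPLATES = (
    "labeled_pair",
    "grouped_panel",
    "condition_distractor",
    "pseudo_table_distractor",
    "term_only",
    "no_term",
)

DEFAULT_MIX = {
    "labeled_pair": 0.40,
    "grouped_panel": 0.20,
    "condition_distractor": 0.15,
    "pseudo_table_distractor": 0.10,
    "term_only": 0.10,
    "no_term": 0.05,
}

#: filler vocabulary guaranteed to contain no dictionary term and no digits.
_FILLER = (
    "patient", "stable", "overnight", "resting", "comfortably", "exam",
    "unremarkable", "today", "reviewed", "plan", "continue", "monitoring",
)

#: per-variable value samplers stay one unit inside the default viable
#: ranges so boundary behavior is tested separately and explicitly.
_LABELED_VARIABLES = (
    "temperature",
    "blood_pressure",
    "heart_rate",
    "respiratory_rate",
    "o2_saturation",
    "ejection_fraction",
    "hba1c",
    "creatinine",
)

#: terms usable in generated text (terms containing '+' cannot survive
#: normalization and are never sampled).
_TERMS = {
    "temperature": ("temp", "t", "fever", "tmax", "temperature"),
    "blood_pressure": ("bp", "b/p", "blood pressure"),
    "heart_rate": ("hr", "pulse", "p"),
    "respiratory_rate": ("rr", "resp.", "r"),
    "o2_saturation": ("sat", "o2sat", "spo2", "saturation", "o2"),
    "ejection_fraction": ("ef", "ejection fraction", "lvef"),
    "hba1c": ("a1c", "hba1c", "hga1c", "hb a1c"),
    "creatinine": ("creat", "cr", "creatinine"),
}

_SEPARATORS = (" ", ": ", ", ", " of ", " is ")


@dataclass
class GeneratorConfig:
    n_notes: int
    seed: int
    mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    unit_prob: float = 0.5

    def __post_init__(self) -> None:
        unknown = set(self.mix) - set(TEMPLATES)
        if unknown:
            raise ValueError(f"unknown template(s) in mix: {sorted(unknown)}")
        total = sum(self.mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"mix weights must sum to 1, got {total}")
        if any(w < 0 for w in self.mix.values()):
            raise ValueError("mix weights must be non-negative")


@dataclass
class SyntheticCorpus:
    notes: list[RawNote]
    gold: list[GoldAnnotation]
    template_labels: list[str]


def _sample_value(variable: str, rng: np.random.Generator):
    """Return (text, value_low, value_high) for one in-range value."""
    if variable == "temperature":
        v = round(rng.uniform(94.0, 109.0), 1)
        return f"{v:.1f}", v, v
    if variable == "blood_pressure":
        sys_v = int(rng.integers(90, 181))
        dia_v = int(rng.integers(50, 111))
        return f"{sys_v}/{dia_v}", float(sys_v), float(dia_v)
    if variable == "heart_rate":
        v = int(rng.integers(40, 141))
        return str(v), float(v), float(v)
    if variable == "respiratory_rate":
        v = int(rng.integers(8, 41))
        return str(v), float(v), float(v)
    if variable == "o2_saturation":
        v = int(rng.integers(85, 100))
        text = f"{v}%" if rng.random() < 0.5 else str(v)
        return text, float(v), float(v)
    if variable == "ejection_fraction":
        if rng.random() < 0.3:
            lo = int(rng.integers(15, 61))
            hi = lo + int(rng.integers(5, 21))
            text = f"{lo}-{hi}%" if rng.random() < 0.5 else f"{lo}-{hi} percent"
            return text, float(lo), float(hi)
        v = int(rng.integers(15, 76))
        text = f"{v} percent" if rng.random() < 0.3 else str(v)
        return text, float(v), float(v)
    if variable == "hba1c":
        v = round(rng.uniform(4.5, 14.0), 1)
        return f"{v:.1f}", v, v
    if variable == "creatinine":
        v = round(rng.uniform(0.4, 9.9), 1)
        return f"{v:.1f}", v, v
    raise ValueError(f"no sampler for variable {variable!r}")


def _filler(rng: np.random.Generator, k: int) -> str:
    return " ".join(rng.choice(_FILLER, size=k, replace=True))


def _labeled_pair(rng, note_id):
    variable = str(rng.choice(_LABELED_VARIABLES))
    term = str(rng.choice(_TERMS[variable]))
    sep = str(rng.choice(_SEPARATORS))
    value_text, lo, hi = _sample_value(variable, rng)
    prefix = _filler(rng, int(rng.integers(0, 3)))
    text = f"{prefix} {term}{sep}{value_text}".strip()
    gold = [GoldAnnotation(note_id, variable, lo, hi)]
    return text, gold


def _grouped_panel(rng, note_id):
    t = round(rng.uniform(94.0, 109.0), 1)
    sys_v = int(rng.integers(90, 181))
    dia_v = int(rng.integers(50, 111))
    hr = int(rng.integers(40, 141))
    rr = int(rng.integers(8, 41))
    o2 = int(rng.integers(85, 100))
    prefix = str(rng.choice(["", "vitals", "vitals:", "vs"]))
    body = f"{t:.1f} {sys_v}/{dia_v} {hr} {rr} {o2}%"
    text = f"{prefix} {body}".strip()
    gold = [
        GoldAnnotation(note_id, "temperature", t, t),
        GoldAnnotation(note_id, "blood_pressure", float(sys_v), float(dia_v)),
        GoldAnnotation(note_id, "heart_rate", float(hr), float(hr)),
        GoldAnnotation(note_id, "respiratory_rate", float(rr), float(rr)),
        GoldAnnotation(note_id, "o2_saturation", float(o2), float(o2)),
    ]
    return text, gold


def _condition_distractor(rng, note_id):
    # reject_conditions vitals only: these must yield zero annotations
    choices = [
        ("fever", round(rng.uniform(100.0, 104.0), 1)),
        ("hr", int(rng.integers(100, 160))),
        ("rr", int(rng.integers(20, 40))),
        ("temp", round(rng.uniform(100.0, 104.0), 1)),
    ]
    term, value = choices[int(rng.integers(0, len(choices)))]
    symbol = str(rng.choice([">", "<", "greater than", "less than"]))
    text = f"{term} {symbol} {value}"
    return text, []


def _pseudo_table_distractor(rng, note_id):
    kind = int(rng.integers(0, 3))
    n = int(rng.integers(3, 6))
    if kind == 0:  # integers >= 300 (violates rule 3)
        values = [str(int(rng.integers(300, 900))) for _ in range(n)]
    elif kind == 1:  # small decimals (violates rule 4, usually rule 2 too)
        values = [f"{rng.uniform(0.5, 80.0):.1f}" for _ in range(n)]
    else:  # hyphen ranges (violate rule 1)
        starts = [int(rng.integers(10, 80)) for _ in range(n)]
        values = [f"{s}-{s + int(rng.integers(2, 10))}" for s in starts]
    return " ".join(values), []


def _term_only(rng, note_id):
    variable = str(rng.choice(_LABELED_VARIABLES))
    term = str(rng.choice(_TERMS[variable]))
    return f"{term} {_filler(rng, 2)}", []


def _no_term(rng, note_id):
    return _filler(rng, int(rng.integers(3, 6))), []


_BUILDERS = {
    "labeled_pair": _labeled_pair,
    "grouped_panel": _grouped_panel,
    "condition_distractor": _condition_distractor,
    "pseudo_table_distractor": _pseudo_table_distractor,
    "term_only": _term_only,
    "no_term": _no_term,
}


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Deterministically generate a corpus from ``config``.

    The same seed always yields a byte-identical corpus.  Gold annotations
    of clean templates are recoverable by the extraction rules; distractor
    templates carry no gold.
    """
    rng = np.random.default_rng(config.seed)
    names = sorted(config.mix)
    weights = np.array([config.mix[n] for n in names], dtype=float)
    weights = weights / weights.sum()

    notes: list[RawNote] = []
    gold: list[GoldAnnotation] = []
    labels: list[str] = []
    for i in range(config.n_notes):
        template = str(rng.choice(names, p=weights))
        note_id = f"note-{i:05d}"
        text, note_gold = _BUILDERS[template](rng, note_id)
        notes.append(RawNote(note_id=note_id, text=text))
        gold.extend(note_gold)
        labels.append(template)
    return SyntheticCorpus(notes=notes, gold=gold, template_labels=labels)


def plant_confusion(
    corpus: SyntheticCorpus,
    a_tp: int,
    b_fp: int,
    c_fn: int,
    d_tn: int,
    seed: int,
    variable: str = "temperature",
) -> tuple[list[GoldAnnotation], list[GoldAnnotation]]:
    """Build (gold', pred') realizing an exact note-level confusion profile.

    The counts must sum to the corpus size.  Mixed false positives (a miss
    plus a spurious value in the same note) are generated sometimes, since
    the scoring rules give FP precedence for those notes.
    """
    n = len(corpus.notes)
    if a_tp + b_fp + c_fn + d_tn != n:
        raise ValueError(
            f"confusion counts sum to {a_tp + b_fp + c_fn + d_tn}, "
            f"corpus has {n} notes"
        )
    if min(a_tp, b_fp, c_fn, d_tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    rng = np.random.default_rng(seed)
    note_ids = [note.note_id for note in corpus.notes]
    order = rng.permutation(n)

    def fresh_value() -> float:
        return round(float(rng.uniform(94.0, 109.0)), 1)

    gold: list[GoldAnnotation] = []
    pred: list[GoldAnnotation] = []
    outcomes = ["tp"] * a_tp + ["fp"] * b_fp + ["fn"] * c_fn + ["tn"] * d_tn
    for pos, outcome in zip(order, outcomes):
        nid = note_ids[pos]
        if outcome == "tp":
            v = fresh_value()
            gold.append(GoldAnnotation(nid, variable, v, v))
            pred.append(GoldAnnotation(nid, variable, v, v))
        elif outcome == "fp":
            v, w = fresh_value(), fresh_value()
            if rng.random() < 0.5:
                pred.append(GoldAnnotation(nid, variable, v, v))
            else:  # mixed: one match plus one spurious — still FP
                gold.append(GoldAnnotation(nid, variable, v, v))
                pred.append(GoldAnnotation(nid, variable, v, v))
                while w == v:
                    w = fresh_value()
                pred.append(GoldAnnotation(nid, variable, w, w))
        elif outcome == "fn":
            v = fresh_value()
            gold.append(GoldAnnotation(nid, variable, v, v))
            if rng.random() < 0.5:
                w = fresh_value()
                while w == v:
                    w = fresh_value()
                gold.append(GoldAnnotation(nid, variable, w, w))
                pred.append(GoldAnnotation(nid, variable, v, v))
        # tn: nothing on either side
    return gold, pred
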