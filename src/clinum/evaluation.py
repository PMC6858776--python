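"""Two-level scoring of predicted annotations against gold annotations.

Note level: a note is a true positive for a variable only if the predicted
value multiset exactly equals the gold multiset (both non-empty); true
negatives are notes where both sides are empty.  A note with any spurious
value is a false positive (this takes precedence over a simultaneous miss);
a note that only misses gold values is a false negative.

Value level: individual values are matched by exact numeric equality (range
endpoints both) within each note; true negatives do not exist at this level,
so specificity and NPV are not reported.

Confidence intervals use the percentile bootstrap over notes, resampled
with replacement B times (default 1000) with an explicit seed.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GoldAnnotation",
    "ConfusionCounts",
    "MetricSet",
    "note_level_outcomes",
    "counts_from_outcomes",
    "note_level_confusion",
    "value_level_confusion",
    "metrics_from_counts",
    "bootstrap_ci",
    "evaluate",
    "NOTE_METRICS",
    "VALUE_METRICS",
]

NOTE_METRICS = ("sensitivity", "specificity", "ppv", "npv", "f1")
VALUE_METRICS = ("sensitivity", "ppv", "f1")

_ROUND = 6  # decimal places used when comparing values


@dataclass(frozen=True)
class GoldAnnotation:
    note_id: str
    variable: str
    value_low: float
    value_high: float

    def __post_init__(self) -> None:
        if self.value_low > self.value_high and self.variable != "blood_pressure":
            raise ValueError("value_low must be <= value_high")


@dataclass
class ConfusionCounts:
    level: str  # "note" | "value"
    variable: str
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int | None = None  # None at value level: no true negatives exist

    def __post_init__(self) -> None:
        if self.level == "value" and self.tn is not None:
            raise ValueError("true negatives are undefined at the value level")


@dataclass
class MetricSet:
    """Point estimates (None when the denominator is zero) plus optional CIs."""

    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    f1: float | None = None
    ci: dict[str, tuple[float, float] | None] = field(default_factory=dict)


def _value_key(low: float, high: float) -> tuple[float, float]:
    return (round(float(low), _ROUND), round(float(high), _ROUND))


def _values_by_note(annotations, variable: str) -> dict[str, Counter]:
    out: dict[str, Counter] = {}
    for ann in annotations:
        if getattr(ann, "variable") != variable:
            continue
        out.setdefault(ann.note_id, Counter())[
            _value_key(ann.value_low, ann.value_high)
        ] += 1
    return out


def note_level_outcomes(
    note_ids,
    gold,
    pred,
    variable: str,
    match: str = "values",
) -> dict[str, str]:
    """Label every note tp/fp/fn/tn for one variable.

    ``match="values"`` compares exact value multisets; ``match="count"``
    only compares how many values each side found (the looser reading).
    """
    if match not in ("values", "count"):
        raise ValueError("match must be 'values' or 'count'")
    gold_by_note = _values_by_note(gold, variable)
    pred_by_note = _values_by_note(pred, variable)
    outcomes: dict[str, str] = {}
    for note_id in note_ids:
        g = gold_by_note.get(note_id, Counter())
        p = pred_by_note.get(note_id, Counter())
        if not g and not p:
            outcomes[note_id] = "tn"
        elif match == "count":
            ng, np_ = sum(g.values()), sum(p.values())
            if ng == np_:
                outcomes[note_id] = "tp"
            elif np_ > ng:
                outcomes[note_id] = "fp"
            else:
                outcomes[note_id] = "fn"
        else:
            spurious = p - g
            missed = g - p
            if not spurious and not missed:
                outcomes[note_id] = "tp"
            elif spurious:
                outcomes[note_id] = "fp"  # precedence over a simultaneous miss
            else:
                outcomes[note_id] = "fn"
    return outcomes


def counts_from_outcomes(outcomes: dict[str, str], variable: str) -> ConfusionCounts:
    counter = Counter(outcomes.values())
    return ConfusionCounts(
        level="note",
        variable=variable,
        tp=counter["tp"],
        fp=counter["fp"],
        fn=counter["fn"],
        tn=counter["tn"],
    )


def note_level_confusion(
    note_ids, gold, pred, variable: str, match: str = "values"
) -> ConfusionCounts:
    return counts_from_outcomes(
        note_level_outcomes(note_ids, gold, pred, variable, match), variable
    )


def value_level_confusion(
    note_ids, gold, pred, variable: str
) -> tuple[ConfusionCounts, list[tuple[int, int, int]]]:
    """Value-level counts plus the per-note (tp, fp, fn) triples used by the
    bootstrap."""
    gold_by_note = _values_by_note(gold, variable)
    pred_by_note = _values_by_note(pred, variable)
    per_note: list[tuple[int, int, int]] = []
    total = ConfusionCounts(level="value", variable=variable)
    for note_id in note_ids:
        g = gold_by_note.get(note_id, Counter())
        p = pred_by_note.get(note_id, Counter())
        tp = sum((g & p).values())
        fp = sum((p - g).values())
        fn = sum((g - p).values())
        per_note.append((tp, fp, fn))
        total.tp += tp
        total.fp += fp
        total.fn += fn
    return total, per_note


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def metrics_from_counts(counts: ConfusionCounts) -> MetricSet:
    """Point estimates from raw counts; undefined ratios become ``None``."""
    tn = counts.tn
    if counts.tp == 0 and counts.fp == 0 and counts.fn == 0 and not tn:
        warnings.warn(
            f"{counts.variable}: all counts zero, no metrics defined", stacklevel=2
        )
        return MetricSet()
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    ppv = _ratio(counts.tp, counts.tp + counts.fp)
    f1 = None
    if sens is not None and ppv is not None and (sens + ppv) > 0:
        f1 = 2 * ppv * sens / (ppv + sens)
    spec = npv = None
    if counts.level == "note" and tn is not None:
        spec = _ratio(tn, tn + counts.fp)
        npv = _ratio(tn, tn + counts.fn)
    return MetricSet(sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, f1=f1)


_LABEL_CODES = {"tp": 0, "fp": 1, "fn": 2, "tn": 3}


def _replicate_metrics_note(tp, fp, fn, tn):
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        ppv = tp / (tp + fp)
        npv = tn / (tn + fn)
        f1 = 2 * ppv * sens / (ppv + sens)
    return {"sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv, "f1": f1}


def bootstrap_ci(
    per_note,
    level: str,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, tuple[float, float] | None]:
    """Percentile-bootstrap CIs over notes.

    ``per_note`` is either a mapping/iterable of outcome labels (note level)
    or a list of ``(tp, fp, fn)`` triples (value level).  The CI for each
    metric is the (alpha/2, 1-alpha/2) percentile pair across ``B``
    replicates; replicates where a metric is undefined are excluded from its
    percentiles.  A fixed seed gives bit-identical output.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)

    if level == "note":
        labels = per_note.values() if isinstance(per_note, dict) else per_note
        arr = np.array([_LABEL_CODES[lab] for lab in labels], dtype=np.int64)
        metric_names = NOTE_METRICS
    elif level == "value":
        arr = np.asarray(list(per_note), dtype=np.int64)
        metric_names = VALUE_METRICS
    else:
        raise ValueError("level must be 'note' or 'value'")

    n = len(arr)
    if n == 0:
        return {name: None for name in metric_names}
    if n < 2:
        warnings.warn("fewer than 2 notes: CIs degenerate to the point estimate",
                      stacklevel=2)

    idx = rng.integers(0, n, size=(B, n))
    if level == "note":
        lab = arr[idx]
        tp = (lab == 0).sum(axis=1).astype(float)
        fp = (lab == 1).sum(axis=1).astype(float)
        fn = (lab == 2).sum(axis=1).astype(float)
        tn = (lab == 3).sum(axis=1).astype(float)
        reps = _replicate_metrics_note(tp, fp, fn, tn)
    else:
        sums = arr[idx].sum(axis=1)  # (B, 3)
        tp, fp, fn = (sums[:, 0].astype(float), sums[:, 1].astype(float),
                      sums[:, 2].astype(float))
        with np.errstate(divide="ignore", invalid="ignore"):
            sens = tp / (tp + fn)
            ppv = tp / (tp + fp)
            f1 = 2 * ppv * sens / (ppv + sens)
        reps = {"sensitivity": sens, "ppv": ppv, "f1": f1}

    cis: dict[str, tuple[float, float] | None] = {}
    for name in metric_names:
        values = reps[name]
        values = values[np.isfinite(values)]
        if values.size == 0:
            cis[name] = None
        else:
            lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            cis[name] = (float(lo), float(hi))
    return cis


def evaluate(
    note_ids,
    gold,
    pred,
    variables=None,
    level: str = "note",
    B: int = 1000,
    seed: int = 0,
    match: str = "values",
) -> pd.DataFrame:
    """Per-variable metric table with bootstrap CIs.

    Returns a DataFrame with one row per variable and columns
    ``variable, level, tp, fp, fn[, tn], <metric>, <metric>_lo, <metric>_hi``.
    CI bounds are clamped so the point estimate always lies inside.
    """
    note_ids = list(note_ids)
    if variables is None:
        variables = sorted(
            {a.variable for a in gold} | {a.variable for a in pred}
        )
    metric_names = NOTE_METRICS if level == "note" else VALUE_METRICS
    rows = []
    for variable in variables:
        if level == "note":
            outcomes = note_level_outcomes(note_ids, gold, pred, variable, match)
            counts = counts_from_outcomes(outcomes, variable)
            per_note = [outcomes[nid] for nid in note_ids]
        else:
            counts, per_note = value_level_confusion(note_ids, gold, pred, variable)
        points = metrics_from_counts(counts)
        cis = bootstrap_ci(per_note, level, B=B, seed=seed)
        row: dict = {
            "variable": variable,
            "level": level,
            "tp": counts.tp,
            "fp": counts.fp,
            "fn": counts.fn,
        }
        if level == "note":
            row["tn"] = counts.tn
        for name in metric_names:
            point = getattr(points, name)
            ci = cis.get(name)
            row[name] = point
            if point is None or ci is None:
                row[f"{name}_lo"] = None
                row[f"{name}_hi"] = None
            else:
                row[f"{name}_lo"] = min(ci[0], point)
                row[f"{name}_hi"] = max(ci[1], point)
        rows.append(row)
    return pd.DataFrame(rows)
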