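"""Per-variable validity testing of extracted candidates.

Each candidate is checked against the variable's allowed value formats,
viable range, condition-symbol policy and unit evidence.  Rejected
candidates are kept with a reason so debug output can explain every drop.
"""

from __future__ import annotations

from dataclasses import dataclass

from .extraction import Candidate, NumericToken, format_ok
from .lexicon import VariableSpec

__all__ = ["ValidityResult", "Annotation", "check_validity", "resolve_unit", "finalize"]

#: units considered compatible with each canonical variable unit.
_COMPATIBLE_UNITS = {
    "°F": {"°F"},
    "%": {"%"},
    "mmHg": {"mmHg"},
    "bpm": {"bpm"},
    "mg/dL": {"mg/dL"},
    "breaths/min": {"breaths/min"},
    "kg": {"kg", "lb"},
    "in": {"in", "cm"},
}


@dataclass
class ValidityResult:
    accepted: bool
    reason: str  # ok | out_of_range | bad_format | condition_rejected | unit_conflict
    inferred_unit: str | None = None
    #: candidate values after normalization (EF decimals rescaled to percent).
    value_low: float | None = None
    value_high: float | None = None


@dataclass(frozen=True)
class Annotation:
    """An accepted extraction, anchored to its note by raw-text offsets."""

    note_id: str
    variable: str
    value_low: float
    value_high: float
    unit: str
    condition: str | None
    char_span: tuple[int, int]
    source: str
    is_fraction: bool = False


def resolve_unit(candidate: Candidate, spec: VariableSpec) -> str | None:
    """Resolve the candidate's unit, or ``None`` on an explicit conflict.

    An explicit adjacent unit token wins; absent that, the unit implied by
    the viable range the value matched (the spec's canonical unit) is used.
    """
    if candidate.unit_hint is None:
        return spec.unit
    compatible = _COMPATIBLE_UNITS.get(spec.unit, {spec.unit})
    if candidate.unit_hint in compatible:
        return candidate.unit_hint
    return None


def check_validity(candidate: Candidate, spec: VariableSpec) -> ValidityResult:
    """Apply format, condition-policy, range and unit rules to one candidate."""
    if candidate.variable != spec.name:
        raise ValueError(
            f"candidate variable {candidate.variable!r} does not match "
            f"spec {spec.name!r}"
        )

    shape = NumericToken(
        surface="",
        value_low=candidate.value_low,
        value_high=candidate.value_high,
        is_fraction=candidate.is_fraction,
        numerator=candidate.numerator,
        denominator=candidate.denominator,
        has_decimal=candidate.has_decimal,
        has_percent=candidate.has_percent,
        is_range=candidate.is_range,
    )
    if not format_ok(spec, shape):
        return ValidityResult(False, "bad_format")

    if candidate.condition is not None and spec.condition_policy == "reject_conditions":
        return ValidityResult(False, "condition_rejected")

    low, high = candidate.value_low, candidate.value_high
    if (
        spec.name == "ejection_fraction"
        and candidate.has_decimal
        and not candidate.is_fraction
        and high <= 1.0
    ):
        # decimal-form EF ("0.55") normalized to the percent scale
        low, high = low * 100.0, high * 100.0

    if candidate.is_fraction:
        lo_ok = _within(candidate.numerator, spec.viable_range)
        hi_ok = _within(
            candidate.denominator, spec.secondary_range or spec.viable_range
        )
        if not (lo_ok and hi_ok):
            return ValidityResult(False, "out_of_range")
    else:
        if not (_within(low, spec.viable_range) and _within(high, spec.viable_range)):
            return ValidityResult(False, "out_of_range")

    unit = resolve_unit(candidate, spec)
    if unit is None:
        return ValidityResult(False, "unit_conflict")

    return ValidityResult(True, "ok", inferred_unit=unit, value_low=low, value_high=high)


def _within(value: float | None, bounds: tuple[float, float]) -> bool:
    return value is not None and bounds[0] <= value <= bounds[1]


def finalize(
    candidates: list[Candidate],
    specs: dict[str, VariableSpec] | list[VariableSpec],
) -> tuple[list[Annotation], list[tuple[Candidate, ValidityResult]]]:
    """Run validity over all candidates.

    Returns ``(annotations, rejects)``: accepted candidates become
    :class:`Annotation` objects sorted by ``(note_id, char_span)``; rejected
    ones are returned alongside their :class:`ValidityResult` for debug
    logging.
    """
    if isinstance(specs, list):
        specs = {s.name: s for s in specs}
    annotations: list[Annotation] = []
    rejects: list[tuple[Candidate, ValidityResult]] = []
    for cand in candidates:
        spec = specs.get(cand.variable)
        if spec is None:
            rejects.append((cand, ValidityResult(False, "bad_format")))
            continue
        result = check_validity(cand, spec)
        if result.accepted:
            annotations.append(
                Annotation(
                    note_id=cand.note_id,
                    variable=cand.variable,
                    value_low=result.value_low,  # type: ignore[arg-type]
                    value_high=result.value_high,  # type: ignore[arg-type]
                    unit=result.inferred_unit or spec.unit,
                    condition=cand.condition,
                    char_span=cand.char_span,
                    source=cand.source,
                    is_fraction=cand.is_fraction,
                )
            )
        else:
            rejects.append((cand, result))
    annotations.sort(key=lambda a: (a.note_id, a.char_span))
    return annotations, rejects
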