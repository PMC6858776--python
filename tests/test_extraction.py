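from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinum.extraction import (
    assign_group,
    extract_note,
    extract_term_adjacent,
    find_number_groups,
    is_vital_group,
    parse_numeric,
)
from clinum.lexicon import match_terms
from clinum.preprocessing import RawNote, canon, normalize, split_sentences, tokenize_sentence

from conftest import make_tokens


def sentence_tokens(text):
    norm = normalize(text)
    spans = split_sentences(norm)
    assert len(spans) == 1
    return tokenize_sentence(norm, spans[0], 0)


def groups_from(text, excluded=frozenset()):
    tokens = sentence_tokens(text)
    numerics = [parse_numeric(t.surface) for t in tokens]
    return find_number_groups(tokens, numerics, set(excluded))


class TestParseNumeric:
    @pytest.mark.parametrize(
        "surface,low,high,kind",
        [
            ("98", 98.0, 98.0, "integer"),
            ("97.0", 97.0, 97.0, "decimal"),
            ("98%", 98.0, 98.0, "percent"),
            ("98.6%", 98.6, 98.6, "percent"),
            ("100/66", 100.0, 66.0, "fraction"),
            ("10-15", 10.0, 15.0, "range"),
            ("35-55%", 35.0, 55.0, "range"),
            ("99.1.", 99.1, 99.1, "decimal"),  # trailing sentence period
        ],
    )
    def test_recognized(self, surface, low, high, kind):
        nt = parse_numeric(surface)
        assert nt is not None
        assert (nt.value_low, nt.value_high) == (low, high)
        if kind == "fraction":
            assert nt.is_fraction and nt.numerator == low and nt.denominator == high
        elif kind == "range":
            assert nt.is_range
        elif kind == "percent":
            assert nt.has_percent
        elif kind == "decimal":
            assert nt.has_decimal and nt.is_plain_integer is False
        else:
            assert nt.is_plain_integer

    @pytest.mark.parametrize(
        "surface", ["abc", "", ".", "/", "%", "a1c", "20-10", "1/2/3", "-5"]
    )
    def test_rejected(self, surface):
        assert parse_numeric(surface) is None

    def test_range_invariant(self):
        nt = parse_numeric("10-15")
        assert nt.value_low <= nt.value_high


class TestTermAdjacent:
    def _extract(self, text, extractor, variable):
        tokens = sentence_tokens(text)
        numerics = [parse_numeric(t.surface) for t in tokens]
        hits = [h for h in match_terms(tokens, extractor.lexicon)
                if h.variable == variable]
        assert hits, f"no {variable} hit in {text!r}"
        spec = extractor.specs[variable]
        out = []
        for hit in hits:
            out.extend(extract_term_adjacent(tokens, numerics, hit, spec))
        return out

    def test_ef_range(self, extractor):
        cands = self._extract(
            "echocardiogram showed ejection fraction 10-15 percent",
            extractor, "ejection_fraction",
        )
        assert len(cands) == 1
        assert (cands[0].value_low, cands[0].value_high) == (10.0, 15.0)
        assert cands[0].has_percent

    def test_condition_recorded_not_consumed(self, extractor):
        cands = self._extract("fever > 100.4", extractor, "temperature")
        assert len(cands) == 1
        assert cands[0].value_low == 100.4
        assert cands[0].condition == ">"

    def test_worded_condition(self, extractor):
        cands = self._extract("ef less than 40", extractor, "ejection_fraction")
        assert cands[0].condition == "<"
        assert cands[0].value_low == 40.0

    def test_no_numeric_in_window(self, extractor):
        cands = self._extract("afebrile overnight", extractor, "temperature")
        assert cands == []

    def test_backward_search(self, extractor):
        cands = self._extract("100/66 bp", extractor, "blood_pressure")
        assert len(cands) == 1
        assert (cands[0].numerator, cands[0].denominator) == (100.0, 66.0)

    def test_format_filter_skips_wrong_shape(self, extractor):
        # bp only accepts fractions: the integer 80 must not be taken
        cands = self._extract("bp was ok hr 80", extractor, "blood_pressure")
        assert cands == []

    def test_window_limit(self, extractor):
        text = "temp checked well patient resting stable comfortable 99.1"
        cands = self._extract(text, extractor, "temperature")
        assert cands == []  # 6 tokens away, beyond the default window of 5


class TestNumberGroups:
    def test_panel_is_one_group_of_five(self):
        groups = groups_from("97.0 100/66 98 18 98%")
        assert len(groups) == 1
        assert len(groups[0].numeric_tokens) == 5

    def test_run_of_two_is_not_a_group(self):
        assert groups_from("1 2") == []

    def test_term_breaks_run(self):
        tokens = sentence_tokens("97.0 100/66 98 18 98%")
        numerics = [parse_numeric(t.surface) for t in tokens]
        # excluding the middle token splits the run into two sub-minimum runs
        groups = find_number_groups(tokens, numerics, {2})
        assert groups == []

    def test_non_numeric_breaks_run(self):
        groups = groups_from("97.0 and 100/66 then 98")
        assert groups == []


class TestIsVitalGroup:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("97.0 100/66 98 18 98%", True),
            ("97.0 100/66 98", True),
            ("98.6 120/80 72", True),
            ("80 18 99", True),
            ("1.2 3.4 5.6", False),   # three decimals, all outside (93, 110)
            ("350 360 370", False),   # integers >= 300
            ("97.0 98.1 99.2 100/66 98", False),  # three '.' tokens
            ("100/66 120/80 98", False),          # two fractions
            ("97% 98% 99", False),                # two percents
            ("10-15 20 30", False),               # '-' violates rule 1
            ("97.0 100/66 98 18 301", False),     # one integer >= 300
            ("45.5 100/66 98", False),            # decimal outside (93, 110)
            ("93.0 100/66 98", False),            # boundary: 93 is not > 93
            ("110.0 100/66 98", False),           # boundary: 110 is not < 110
        ],
    )
    def test_rules(self, text, expected):
        groups = groups_from(text)
        assert len(groups) == 1
        assert is_vital_group(groups[0]) is expected


class TestAssignGroup:
    def _assign(self, text, specs_by_name):
        groups = groups_from(text)
        assert len(groups) == 1
        cands = assign_group(groups[0], specs_by_name)
        return {c.variable: (c.value_low, c.value_high) for c in cands}

    def test_full_panel(self, specs_by_name):
        assigned = self._assign("97.0 100/66 98 18 98%", specs_by_name)
        assert assigned == {
            "temperature": (97.0, 97.0),
            "blood_pressure": (100.0, 66.0),
            "heart_rate": (98.0, 98.0),
            "respiratory_rate": (18.0, 18.0),
            "o2_saturation": (98.0, 98.0),
        }

    def test_partial_panel(self, specs_by_name):
        assigned = self._assign("98.6 120/80 72", specs_by_name)
        assert assigned == {
            "temperature": (98.6, 98.6),
            "blood_pressure": (120.0, 80.0),
            "heart_rate": (72.0, 72.0),
        }

    def test_three_integers_positional(self, specs_by_name):
        assigned = self._assign("80 18 99", specs_by_name)
        assert assigned == {
            "heart_rate": (80.0, 80.0),
            "respiratory_rate": (18.0, 18.0),
            "o2_saturation": (99.0, 99.0),
        }

    def test_variable_filled_at_most_once(self, specs_by_name):
        # two temperature-window decimals: only the first is assigned
        assigned = self._assign("97.0 98.2 100/66 98", specs_by_name)
        assert assigned["temperature"] == (97.0, 97.0)
        values = list(assigned.values())
        assert len(values) == len(set(values))

    def test_out_of_range_integer_unassigned(self, specs_by_name):
        # 2 sits below every positional variable's range
        assigned = self._assign("2 80 18 99", specs_by_name)
        assert assigned == {
            "heart_rate": (80.0, 80.0),
            "respiratory_rate": (18.0, 18.0),
            "o2_saturation": (99.0, 99.0),
        }

    @given(pos=st.integers(0, 3))
    @settings(max_examples=20, deadline=None)
    def test_distractor_position_invariance(self, pos, specs_by_name):
        # a non-signature-bearing token ("2") moved around the panel never
        # changes the assignment of the signature-bearing tokens
        parts = ["97.0", "100/66", "84"]
        parts.insert(pos, "2")
        assigned = self._assign(" ".join(parts), specs_by_name)
        assert assigned == {
            "temperature": (97.0, 97.0),
            "blood_pressure": (100.0, 66.0),
            "heart_rate": (84.0, 84.0),
        }


class TestExtractNote:
    def test_panel_note_five_candidates(self, extractor):
        cands = extractor.candidates(RawNote("n1", "vitals: 97.0 100/66 98 18 98%"))
        assert len(cands) == 5
        assert {c.variable for c in cands} == {
            "temperature", "blood_pressure", "heart_rate",
            "respiratory_rate", "o2_saturation",
        }

    def test_empty_note(self, extractor):
        assert extractor.candidates(RawNote("n1", "")) == []

    def test_repeated_measurements_both_kept(self, extractor):
        cands = extractor.candidates(RawNote("n1", "temp 99.1 and later temp 100.8"))
        temps = [c for c in cands if c.variable == "temperature"]
        assert sorted(c.value_low for c in temps) == [99.1, 100.8]
        assert temps[0].char_span != temps[1].char_span

    def test_term_adjacent_consumes_token_from_groups(self, extractor):
        # bp claims 120/80; the remaining run of three still forms a group
        cands = extractor.candidates(RawNote("n1", "bp 120/80 98 18 97%"))
        by_var = {c.variable: c for c in cands}
        assert by_var["blood_pressure"].source == "term_adjacent"
        assert by_var["heart_rate"].source == "number_group"
        assert by_var["heart_rate"].value_low == 98.0
        assert by_var["respiratory_rate"].value_low == 18.0
        assert by_var["o2_saturation"].value_low == 97.0

    def test_char_span_slices_value_digits(self, extractor):
        note = RawNote("n1", "Vitals: T 98.6, BP 120/80; sat 97%")
        for cand in extractor.candidates(note):
            segment = note.text[cand.char_span[0]:cand.char_span[1]]
            digits = "".join(ch for ch in segment if ch.isdigit())
            expected = "".join(ch for ch in str(cand.value_low) if ch.isdigit())
            assert expected.rstrip("0") in digits or expected in digits

    def test_no_numeric_token_yields_two_candidates(self, extractor):
        # one value claimed by a term is excluded from groups entirely
        cands = extractor.candidates(RawNote("n1", "temp 98.6 120/80 84 16"))
        spans = [c.char_span for c in cands]
        assert len(spans) == len(set(spans))

    def test_nearest_term_wins_competition(self, extractor):
        cands = extractor.candidates(RawNote("n1", "temp 99.1 pulse 84"))
        by_var = {c.variable: c.value_low for c in cands}
        assert by_var == {"temperature": 99.1, "heart_rate": 84.0}

    def test_tie_prefers_forward_direction(self, extractor):
        # "84" is 1 token after "hr" and 1 token before "rr": hr wins the tie
        cands = extractor.candidates(RawNote("n1", "hr 84 rr"))
        assert [(c.variable, c.value_low) for c in cands] == [("heart_rate", 84.0)]
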