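# clinum

Rule-based extraction of numerical clinical parameters — vital signs
(temperature, blood pressure, heart rate, respiratory rate, oxygen
saturation), ejection fraction, HbA1C, creatinine, height and weight — from
narrative clinical notes, together with a two-level evaluation harness
(note level and value level, with percentile-bootstrap confidence
intervals) and a synthetic-note generator so the whole pipeline can be
exercised without any real medical records.

## How it works

1. **Preprocessing** — notes are lowercased, grammatical punctuation is
   blanked out (length-preserving, so character offsets always point into
   the raw text), sentences are segmented (guarding decimals like `101.2`
   and dictionary abbreviations like `resp.`), and tokens are filtered
   against a stop-word list from which dictionary terms (`t`, `s`, …) are
   protected.
2. **Term matching** — per-variable term dictionaries (shipped in
   `src/clinum/data/default_variables.yaml`) are matched over whole tokens
   with a prefix tree; the longest match at each position wins.
3. **Extraction** — two categories:
   * *term-adjacent*: the nearest valid-format numeric token in the same
     sentence (forward first, then backward, within a 5-token window);
     ranges (`10-15 percent`), fractions (`132/78`) and percents are
     recognized, and inequality words/symbols between term and value are
     recorded as a condition rather than consumed;
   * *number groups*: runs of ≥3 unlabeled numeric tokens
     (`97.0 100/66 98 18 98%`) are screened by plausibility rules (only
     `./%` characters, limited fraction/percent/decimal counts, integers
     < 300, decimals inside the body-temperature window) and then assigned
     positionally to the T / BP / HR / RR / O2-sat panel.
4. **Validity testing** — viable range (both endpoints for ranges, both
   components for blood pressure), value-format rules, per-variable
   condition policy (conditions rejected for vital signs, accepted and
   recorded for EF/HbA1C), decimal-form EF rescaling (0.55 → 55 %), and
   unit inference/conflict detection.

Notes on the shipped dictionaries: they are reproduced verbatim from the
published tool's dictionary table, including its apparent typos (e.g.
`tear` under temperature, `tachypea` under respiratory rate); one garbled
quoting artifact in the glycated-hemoglobin row was split into the two
plain terms `glycosylated hemoglobin a` and `glycosylated hemoglobins`.
Every list, range and policy can be overridden with a YAML config (see
`clinum validate-config`). The published workflow for building new
dictionaries (query UMLS or an acronym database for synonyms and
abbreviations, then review a small corpus of notes and add the terms
clinicians actually use) is manual and is not automated here. Height and
weight ranges are unvalidated placeholders.

## CLI

```sh
# generate a synthetic corpus with gold annotations
clinum simulate --n 200 --seed 7 --out notes.jsonl --gold gold.csv

# run extraction (txt dir, JSONL or CSV input; CSV/JSONL output)
clinum extract --input notes.jsonl --out pred.csv --debug rejected.jsonl

# score predictions at the note or value level
clinum evaluate --pred pred.csv --gold gold.csv --notes notes.jsonl \
    --level note -B 1000 --seed 1 --out metrics.csv

# sanity-check a custom variable config
clinum validate-config my_variables.yaml
```

Output rows are `note_id, variable, value_low, value_high, unit,
condition, start, end, source, is_fraction`; `start`/`end` are 0-based
half-open offsets into the raw note text. For blood pressure,
`value_low` is systolic and `value_high` diastolic with
`is_fraction=true`.

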