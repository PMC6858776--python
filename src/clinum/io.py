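"""Readers and writers for notes, annotations, gold files and metric tables.

Formats are deliberately plain: UTF-8 text files, JSONL and RFC-4180 CSV
with a mandatory header row.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .evaluation import GoldAnnotation
from .preprocessing import RawNote
from .validity import Annotation

logger = logging.getLogger("clinum")

ANNOTATION_COLUMNS = [
    "note_id",
    "variable",
    "value_low",
    "value_high",
    "unit",
    "condition",
    "start",
    "end",
    "source",
    "is_fraction",
]


def detect_format(path: str | Path) -> str:
    path = Path(path)
    if path.is_dir():
        return "txt-dir"
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson"):
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer input format from {path}; pass --format")


def iter_notes(path: str | Path, fmt: str | None = None) -> Iterator[RawNote]:
    """Yield notes from a directory of .txt files, a JSONL file or a CSV.

    A single malformed record is skipped with a warning rather than
    aborting the run.
    """
    path = Path(path)
    fmt = fmt or detect_format(path)
    if fmt == "txt-dir":
        for file in sorted(path.glob("*.txt")):
            try:
                yield RawNote(note_id=file.stem, text=file.read_text("utf-8"))
            except (OSError, UnicodeDecodeError) as exc:
                logger.warning("skipping unreadable note %s: %s", file, exc)
    elif fmt == "jsonl":
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                    yield RawNote(note_id=str(record["note_id"]),
                                  text=str(record["text"]))
                except (json.JSONDecodeError, KeyError, ValueError) as exc:
                    logger.warning("skipping malformed record at %s:%d: %s",
                                   path, lineno, exc)
    elif fmt == "csv":
        frame = pd.read_csv(path, dtype={"note_id": str, "text": str})
        missing = {"note_id", "text"} - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        for _, row in frame.iterrows():
            text = row["text"] if isinstance(row["text"], str) else ""
            yield RawNote(note_id=str(row["note_id"]), text=text)
    else:
        raise ValueError(f"unknown input format {fmt!r}")


def write_notes_jsonl(notes: Iterable[RawNote], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(json.dumps({"note_id": note.note_id, "text": note.text}) + "\n")


def _annotation_row(ann: Annotation) -> dict:
    return {
        "note_id": ann.note_id,
        "variable": ann.variable,
        "value_low": ann.value_low,
        "value_high": ann.value_high,
        "unit": ann.unit,
        "condition": ann.condition or "",
        "start": ann.char_span[0],
        "end": ann.char_span[1],
        "source": ann.source,
        "is_fraction": ann.is_fraction,
    }


def write_annotations(
    annotations: Iterable[Annotation], path: str | Path, fmt: str = "csv"
) -> None:
    rows = [_annotation_row(a) for a in annotations]
    if fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=ANNOTATION_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
    elif fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    else:
        raise ValueError(f"unknown output format {fmt!r}")


def read_annotations(path: str | Path, fmt: str | None = None) -> list[Annotation]:
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson") else "csv"
    rows: list[dict]
    if fmt == "csv":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh))
    else:
        with open(path, "r", encoding="utf-8") as fh:
            rows = [json.loads(line) for line in fh if line.strip()]
    out = []
    for row in rows:
        out.append(
            Annotation(
                note_id=str(row["note_id"]),
                variable=str(row["variable"]),
                value_low=float(row["value_low"]),
                value_high=float(row["value_high"]),
                unit=str(row["unit"]),
                condition=(row.get("condition") or None),
                char_span=(int(row["start"]), int(row["end"])),
                source=str(row["source"]),
                is_fraction=str(row.get("is_fraction", "")).lower() == "true",
            )
        )
    return out


def read_gold(path: str | Path) -> list[GoldAnnotation]:
    """Gold CSV: note_id,variable,value_low,value_high (high may be blank)."""
    out = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            low = float(row["value_low"])
            high_raw = row.get("value_high", "")
            high = float(high_raw) if high_raw not in ("", None) else low
            out.append(
                GoldAnnotation(
                    note_id=str(row["note_id"]),
                    variable=str(row["variable"]),
                    value_low=low,
                    value_high=high,
                )
            )
    return out


def write_gold(gold: Iterable[GoldAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["note_id", "variable", "value_low", "value_high"])
        for g in gold:
            writer.writerow([g.note_id, g.variable, g.value_low, g.value_high])


def format_metrics_table(frame: pd.DataFrame) -> str:
    """Pretty metric table with '0.94 (0.90, 0.98)' style cells."""
    metric_names = [
        c for c in ("sensitivity", "specificity", "ppv", "npv", "f1")
        if c in frame.columns
    ]
    display = frame[["variable"]].copy()
    for name in metric_names:
        cells = []
        for _, row in frame.iterrows():
            if pd.isna(row[name]):
                cells.append("--")
            elif pd.isna(row.get(f"{name}_lo")):
                cells.append(f"{row[name]:.2f}")
            else:
                cells.append(
                    f"{row[name]:.2f} ({row[f'{name}_lo']:.2f}, "
                    f"{row[f'{name}_hi']:.2f})"
                )
        display[name] = cells
    return display.to_string(index=False)
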