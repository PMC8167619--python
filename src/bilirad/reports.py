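"""Report container and JSONL/CSV persistence.

A :class:`Report` is the unit flowing through the whole pipeline: one
free-text radiology report (mixed Hangul/Latin script) with an id, a
modality and an optional three-class pneumonia label.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence


class Label(Enum):
    """Document-level pneumonia status. Class order is fixed and used for
    argmax tie-breaking and confusion-matrix axes throughout."""

    NEGATIVE = 0
    POSITIVE = 1
    OBSCURE = 2

    @classmethod
    def from_string(cls, s: str) -> "Label":
        try:
            return cls[s.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown label string: {s!r}") from None


#: fixed class order (NEGATIVE, POSITIVE, OBSCURE)
LABELS: tuple[Label, ...] = (Label.NEGATIVE, Label.POSITIVE, Label.OBSCURE)


class Modality(Enum):
    CT = "CT"
    XRAY = "XRAY"
    OTHER = "OTHER"

    @classmethod
    def from_string(cls, s: str) -> "Modality":
        try:
            return cls[s.strip().upper()]
        except KeyError:
            return cls.OTHER


@dataclass(frozen=True)
class Report:
    id: str
    modality: Modality
    text: str
    label: Optional[Label] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("report id must be non-empty")


class ReportFormatError(ValueError):
    """Raised on malformed report files; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


_FIELDS = ("id", "modality", "text", "label")


def _report_to_dict(r: Report) -> dict:
    return {
        "id": r.id,
        "modality": r.modality.value,
        "text": r.text,
        "label": r.label.name.lower() if r.label is not None else None,
    }


def _report_from_dict(d: dict, line: int) -> Report:
    for key in ("id", "modality", "text"):
        if key not in d or d[key] is None:
            raise ReportFormatError(f"missing field {key!r}", line)
    label = d.get("label")
    if label in (None, ""):
        parsed = None
    else:
        try:
            parsed = Label.from_string(str(label))
        except ValueError as exc:
            raise ReportFormatError(str(exc), line) from None
    return Report(
        id=str(d["id"]),
        modality=Modality.from_string(str(d["modality"])),
        text=str(d["text"]),
        label=parsed,
    )


def write_reports(reports: Iterable[Report], path: str | Path, format: str = "jsonl") -> None:
    """Write reports as UTF-8 JSONL (one object per line) or CSV."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in reports:
                fh.write(json.dumps(_report_to_dict(r), ensure_ascii=False) + "\n")
    elif fmt == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_FIELDS)
            writer.writeheader()
            for r in reports:
                d = _report_to_dict(r)
                d["label"] = d["label"] or ""
                writer.writerow(d)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'jsonl' or 'csv')")


def read_reports(path: str | Path, format: str | None = None) -> list[Report]:
    """Read reports from JSONL or CSV; format inferred from suffix if omitted.

    Malformed lines raise :class:`ReportFormatError` naming the line number.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    out: list[Report] = []
    if fmt == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    d = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ReportFormatError(f"invalid JSON: {exc}", i) from None
                if not isinstance(d, dict):
                    raise ReportFormatError("JSONL line is not an object", i)
                out.append(_report_from_dict(d, i))
    elif fmt == "csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for i, row in enumerate(reader, start=2):  # header is line 1
                out.append(_report_from_dict(row, i))
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'jsonl' or 'csv')")
    return out
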