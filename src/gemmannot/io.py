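"""Readers, writers and data cleaning for composition files and annotations.

Two input dialects are accepted and normalized to one internal form: the
angle-bracket MGI dialect (``Mybl2<tm1.1Epr>``) and the caret/superscript
rendering common in running text (``Mybl2^tm1.1Epr^``). Deduplication keys
on the canonical serialization, so trivially re-spaced duplicates collapse;
unparseable records are routed to a rejects list, never dropped silently.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple

from .annotate import annotate_composition
from .errors import ColumnMissingError, FileMissingError, GemmannotError, WriteError
from .knowledge import KnowledgeTable
from .nomenclature import format_composition, parse_composition

__all__ = [
    "AnnotationRecord",
    "normalize_dialect",
    "read_compositions",
    "deduplicate_records",
    "build_record",
    "write_annotations",
    "read_annotations",
    "TSV_COLUMNS",
]

_CARET_RE = re.compile(r"\^([^\^\s]+)\^")

TSV_COLUMNS = [
    "raw_composition",
    "canonical",
    "categories",
    "annotation",
    "provenance",
    "tissues",
    "needs_manual",
]


@dataclass
class AnnotationRecord:
    """One annotated composition, serializable to a TSV row or JSON object."""

    raw: str
    canonical: str
    categories: List[str] = field(default_factory=list)
    annotation: str = ""
    provenance: str = "machine"
    tissues: List[str] = field(default_factory=list)
    needs_manual: bool = False

    def to_json_obj(self) -> dict:
        return {
            "raw_composition": self.raw,
            "canonical": self.canonical,
            "categories": self.categories,
            "annotation": self.annotation,
            "provenance": self.provenance,
            "tissues": self.tissues,
            "needs_manual": self.needs_manual,
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "AnnotationRecord":
        return cls(
            raw=obj["raw_composition"],
            canonical=obj["canonical"],
            categories=list(obj["categories"]),
            annotation=obj["annotation"],
            provenance=obj["provenance"],
            tissues=list(obj["tissues"]),
            needs_manual=bool(obj["needs_manual"]),
        )

    def to_tsv_row(self) -> List[str]:
        return [
            self.raw,
            self.canonical,
            "|".join(self.categories),
            self.annotation,
            self.provenance,
            "|".join(self.tissues),
            "1" if self.needs_manual else "0",
        ]

    @classmethod
    def from_tsv_row(cls, row: List[str]) -> "AnnotationRecord":
        return cls(
            raw=row[0],
            canonical=row[1],
            categories=row[2].split("|") if row[2] else [],
            annotation=row[3],
            provenance=row[4],
            tissues=row[5].split("|") if row[5] else [],
            needs_manual=row[6] == "1",
        )


def normalize_dialect(text: str) -> str:
    """Rewrite caret-superscript alleles to the angle-bracket dialect."""
    return _CARET_RE.sub(r"<\1>", text)


def read_compositions(
    path: str | Path, column: str = "allele_composition"
) -> List[str]:
    """Read composition strings from a TSV (by *column*) or plain-text file.

    A file whose first line contains *column* among its tab-separated fields
    is read as TSV; any other file is one composition per line. Blank lines
    are skipped; caret dialect is normalized; order is preserved.
    """
    p = Path(path)
    if not p.is_file():
        raise FileMissingError(f"input file not found: {path}")
    lines = p.read_text(encoding="utf-8").splitlines()
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    if column in header:
        idx = header.index(column)
        out = []
        for line in lines[1:]:
            if not line.strip():
                continue
            fields = line.split("\t")
            value = fields[idx].strip() if idx < len(fields) else ""
            if value:
                out.append(normalize_dialect(value))
        return out
    if "\t" in lines[0]:
        raise ColumnMissingError(
            f"column {column!r} not found in header {header}"
        )
    return [
        normalize_dialect(line.strip()) for line in lines if line.strip()
    ]


def deduplicate_records(records: List[str]) -> Tuple[List[str], List[str]]:
    """Keep the first occurrence of each composition by canonical form.

    Returns ``(kept, rejects)``; unparseable strings go to *rejects*.
    """
    kept: List[str] = []
    rejects: List[str] = []
    seen: set[str] = set()
    for raw in records:
        try:
            canonical = format_composition(parse_composition(normalize_dialect(raw)))
        except GemmannotError:
            rejects.append(raw)
            continue
        if canonical not in seen:
            seen.add(canonical)
            kept.append(raw)
    return kept, rejects


def build_record(raw: str, kb: KnowledgeTable) -> AnnotationRecord:
    """Parse and annotate one composition string into a record."""
    comp = parse_composition(normalize_dialect(raw))
    ann = annotate_composition(comp, kb)
    return AnnotationRecord(
        raw=raw,
        canonical=format_composition(comp),
        categories=[cat.value for cat, _ in ann.per_subcomposition],
        annotation=ann.text,
        provenance=ann.provenance.value,
        tissues=list(ann.tissues_mentioned),
        needs_manual=ann.needs_manual,
    )


def write_annotations(
    path: str | Path, records: List[AnnotationRecord], format: str = "tsv"
) -> None:
    """Write records as TSV (fixed column order) or a JSON array."""
    p = Path(path)
    try:
        if format == "tsv":
            with open(p, "w", encoding="utf-8", newline="") as fh:
                writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
                writer.writerow(TSV_COLUMNS)
                for rec in records:
                    writer.writerow(rec.to_tsv_row())
        elif format == "json":
            with open(p, "w", encoding="utf-8") as fh:
                json.dump([r.to_json_obj() for r in records], fh,
                          indent=2, ensure_ascii=False)
                fh.write("\n")
        else:
            raise ValueError(f"unknown format {format!r}")
    except OSError as exc:
        raise WriteError(f"cannot write {path}: {exc}") from exc


def read_annotations(path: str | Path, format: str = "tsv") -> List[AnnotationRecord]:
    p = Path(path)
    if not p.is_file():
        raise FileMissingError(f"annotation file not found: {path}")
    if format == "json":
        with open(p, encoding="utf-8") as fh:
            return [AnnotationRecord.from_json_obj(o) for o in json.load(fh)]
    with open(p, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = list(reader)
    return [AnnotationRecord.from_tsv_row(r) for r in rows[1:]]
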