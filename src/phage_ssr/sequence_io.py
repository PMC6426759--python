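"""Genome and annotation I/O.

Reads genomes from FASTA and coding intervals from GenBank flat files, and
writes every pipeline table as tab-separated text. All serialized coordinates
are 1-based inclusive (the GenBank convention); 0-based half-open coordinates
are permitted only transiently inside computations.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import FormatError

logger = logging.getLogger(__name__)

#: Residues kept verbatim; every other (IUPAC ambiguity) letter becomes N.
_CANONICAL = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """One genome: identifier, residues, length and GC fraction.

    ``gc_fraction`` is (#G + #C) / (#A + #C + #G + #T); N positions are
    excluded from the denominator, and an all-N sequence reports 0.
    """

    id: str
    seq: str
    length: int = field(init=False)
    gc_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "length", len(self.seq))
        gc = self.seq.count("G") + self.seq.count("C")
        acgt = self.length - self.seq.count("N")
        object.__setattr__(self, "gc_fraction", gc / acgt if acgt else 0.0)

    @classmethod
    def from_raw(cls, identifier: str, raw: str) -> "SequenceRecord":
        """Build a record from raw residues, uppercasing and mapping
        ambiguity codes to N (the number of replacements is logged)."""
        up = raw.upper()
        cleaned = "".join(c if c in _CANONICAL else "N" for c in up)
        n_replaced = sum(1 for a, b in zip(up, cleaned) if a != b)
        if n_replaced:
            logger.warning(
                "record %s: %d ambiguity code(s) mapped to N", identifier, n_replaced
            )
        return cls(id=identifier, seq=cleaned)


@dataclass(frozen=True)
class CdsInterval:
    """A named coding interval, 1-based inclusive."""

    label: str
    start: int
    end: int
    strand: str = "+"
    compound_location: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"interval {self.label!r}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"interval {self.label!r}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnnotationTable:
    """Coding intervals for one genome, sorted by start (overlaps are legal)."""

    genome_id: str
    intervals: tuple[CdsInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "intervals", tuple(sorted(self.intervals, key=lambda c: (c.start, c.end)))
        )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read one or more genomes from a FASTA file.

    Residues are uppercased; IUPAC ambiguity codes become N. An empty file or
    a zero-length record raises :class:`FormatError`.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has no residues")
        records.append(SequenceRecord.from_raw(rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.seq[i : i + width] + "\n")


def _feature_label(feat, ordinal: int) -> str:
    for key in ("gene", "product", "locus_tag"):
        vals = feat.qualifiers.get(key)
        if vals and str(vals[0]).strip():
            return str(vals[0]).strip()
    return f"CDS_{ordinal}"


def read_genbank_features(
    path: str | Path, feature_kinds: frozenset[str] | set[str] = frozenset({"CDS"})
) -> AnnotationTable:
    """Extract coding intervals from a GenBank flat file.

    join/complement locations are collapsed to their spanning interval
    (minimal to maximal coordinate), flagged via ``compound_location``.
    Label priority: /gene, then /product, then /locus_tag, then ordinal.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8", errors="replace")
    if "FEATURES" not in text:
        raise FormatError(f"{path}: no FEATURES section")
    record = SeqIO.read(str(path), "genbank")
    seq_len = len(record.seq)
    intervals: list[CdsInterval] = []
    ordinal = 0
    for feat in record.features:
        if feat.type not in feature_kinds:
            continue
        ordinal += 1
        start = int(feat.location.start) + 1  # biopython is 0-based half-open
        end = int(feat.location.end)
        if seq_len and end > seq_len:
            raise FormatError(
                f"{path}: feature {ordinal} location {start}..{end} exceeds "
                f"sequence length {seq_len}"
            )
        strand = "-" if feat.location.strand == -1 else "+"
        compound = len(getattr(feat.location, "parts", [None])) > 1
        intervals.append(
            CdsInterval(
                label=_feature_label(feat, ordinal),
                start=start,
                end=end,
                strand=strand,
                compound_location=compound,
            )
        )
    return AnnotationTable(genome_id=record.id or path.stem, intervals=tuple(intervals))


def write_table(rows: Sequence, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records (dataclasses or dicts) as a TSV with header.

    Zero rows yields a header-only file when ``columns`` is given, or an
    empty file otherwise. Coordinates are serialized 1-based inclusive, as
    stored on the records themselves.
    """
    rows = list(rows)
    dict_rows: list[dict] = []
    for r in rows:
        if dataclasses.is_dataclass(r) and not isinstance(r, type):
            dict_rows.append(dataclasses.asdict(r))
        elif isinstance(r, dict):
            dict_rows.append(r)
        else:
            raise TypeError(f"unsupported row type {type(r).__name__}")
    if columns is None:
        columns = list(dict_rows[0].keys()) if dict_rows else []
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t", extrasaction="ignore")
        if columns:
            writer.writeheader()
        for d in dict_rows:
            writer.writerow({k: d.get(k, "") for k in columns})
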