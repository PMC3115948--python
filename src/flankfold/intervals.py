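"""Genomic data model and annotation I/O.

All coordinates are 0-based, half-open (``[start, end)``), regardless of the
dialect of the file they came from; GFF's 1-based inclusive coordinates are
converted on ingest. All distances downstream of these types are differences
of boundary positions and therefore exact integers.

The central asymmetry of the pipeline is transcription orientation: a
feature's 3' boundary is ``end`` on the plus strand and ``start`` on the
minus strand. EST alignments expose both of their endpoints ("termini"), the
raw observable that oligo-dT-primed cDNA sequencing leaves next to a cleaved
hairpin's 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

__all__ = [
    "GenomicInterval",
    "MirnaAnnotation",
    "EstRecord",
    "Terminus",
    "read_intervals",
    "write_bed",
    "read_est_table",
    "write_est_table",
    "read_chrom_sizes",
    "three_prime_boundary",
    "five_prime_boundary",
    "est_termini",
]

Strand = Literal["+", "-", "."]


class FormatError(ValueError):
    """A file did not parse under the declared dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded (or unstranded, ``strand='.'``) genomic interval.

    ``start < end`` is required: zero-length intervals carry no sequence and
    are rejected so that boundary arithmetic stays unambiguous.
    """

    chrom: str
    start: int
    end: int
    strand: Strand = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def stranded(self) -> bool:
        return self.strand in ("+", "-")


@dataclass(frozen=True)
class MirnaAnnotation:
    """A known miRNA: the pre-miRNA hairpin locus plus nested mature arms."""

    id: str
    locus: GenomicInterval
    matures: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        for m in self.matures:
            if m.chrom != self.locus.chrom:
                raise ValueError(f"{self.id}: mature on different chromosome")
            if not (self.locus.start <= m.start and m.end <= self.locus.end):
                raise ValueError(f"{self.id}: mature {m} not nested in locus")
            if m.strand != self.locus.strand:
                raise ValueError(f"{self.id}: mature strand differs from locus")


@dataclass(frozen=True)
class EstRecord:
    """One aligned EST with its library/tissue annotation.

    Tissue labels are lower-cased free text; matching elsewhere is
    case-insensitive exact-string, with no ontology mapping.
    """

    id: str
    align: GenomicInterval
    library_id: str = ""
    tissues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "tissues", frozenset(t.strip().lower() for t in self.tissues if t.strip())
        )


@dataclass(frozen=True)
class Terminus:
    """One endpoint of an EST alignment, tagged with which end it is."""

    position: int
    est: EstRecord
    which: Literal["start", "end"]


def three_prime_boundary(iv: GenomicInterval) -> int:
    """Boundary position of the interval's 3' end in transcription direction.

    Half-open convention: the boundary is between bases, so a plus-strand
    interval's 3' boundary is ``end`` and a minus-strand interval's is
    ``start``.
    """
    if iv.strand == "+":
        return iv.end
    if iv.strand == "-":
        return iv.start
    raise ValueError(f"3' boundary undefined for unstranded interval {iv}")


def five_prime_boundary(iv: GenomicInterval) -> int:
    """Boundary position of the interval's 5' end (mirror of the 3' rule)."""
    if iv.strand == "+":
        return iv.start
    if iv.strand == "-":
        return iv.end
    raise ValueError(f"5' boundary undefined for unstranded interval {iv}")


def est_termini(est: EstRecord) -> tuple[Terminus, Terminus]:
    """Both endpoints of an EST alignment, each tagged with its end.

    EST strand is deliberately not consulted: dbEST orientation is
    unreliable, so both genomic endpoints are candidate traces of a
    reverse-transcription stop. No deduplication is performed when two ESTs
    share an endpoint.
    """
    return (
        Terminus(est.align.start, est, "start"),
        Terminus(est.align.end, est, "end"),
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise FormatError(f"line {lineno}: BED needs >= 3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer BED coordinate") from exc
    name = fields[3] if len(fields) > 3 else ""
    strand: Strand = "."
    if len(fields) > 5 and fields[5] in ("+", "-"):
        strand = fields[5]  # type: ignore[assignment]
    try:
        return GenomicInterval(chrom, start, end, strand, name)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: {exc}") from exc


def _parse_gff_line(line: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 7:
        raise FormatError(f"line {lineno}: GFF needs >= 7 tab-separated fields")
    chrom = fields[0]
    try:
        start1, end1 = int(fields[3]), int(fields[4])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer GFF coordinate") from exc
    strand: Strand = fields[6] if fields[6] in ("+", "-") else "."  # type: ignore[assignment]
    name = ""
    if len(fields) > 8:
        for attr in fields[8].split(";"):
            key, _, value = attr.strip().partition("=")
            if key in ("ID", "Name"):
                name = value
                break
    try:
        # GFF is 1-based inclusive; convert to 0-based half-open.
        return GenomicInterval(chrom, start1 - 1, end1, strand, name)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: {exc}") from exc


def _parse_tsv_line(line: str, lineno: int) -> GenomicInterval:
    # Generic interval TSV: name chrom start end strand
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 4:
        raise FormatError(f"line {lineno}: interval TSV needs >= 4 fields")
    name, chrom = fields[0], fields[1]
    try:
        start, end = int(fields[2]), int(fields[3])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer coordinate") from exc
    strand: Strand = "."
    if len(fields) > 4 and fields[4] in ("+", "-"):
        strand = fields[4]  # type: ignore[assignment]
    try:
        return GenomicInterval(chrom, start, end, strand, name)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: {exc}") from exc


_PARSERS = {"bed": _parse_bed_line, "gff": _parse_gff_line, "tsv": _parse_tsv_line}


def read_intervals(path: str | Path, format: str = "bed") -> list[GenomicInterval]:
    """Read genomic intervals from BED6, GFF3 or the native interval TSV.

    Coordinates are normalised to 0-based half-open regardless of the source
    dialect. Comment (``#``), ``track`` and ``browser`` lines are skipped.
    Malformed lines raise :class:`FormatError` naming the line number.
    """
    if format not in _PARSERS:
        raise ValueError(f"unknown interval format {format!r}; expected bed/gff/tsv")
    parse = _PARSERS[format]
    out: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            out.append(parse(line, lineno))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (round-trips bit-exactly through read_intervals)."""
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


EST_TSV_COLUMNS = ["est_id", "chrom", "start", "end", "strand", "library_id", "tissues"]


def read_est_table(path: str | Path) -> list[EstRecord]:
    """Read the EST TSV dialect.

    Header ``est_id chrom start end strand library_id tissues``; the tissues
    column holds semicolon-separated labels and may be empty.
    """
    records: list[EstRecord] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[: len(EST_TSV_COLUMNS)] != EST_TSV_COLUMNS:
            raise FormatError(
                f"line 1: expected EST TSV header {EST_TSV_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise FormatError(f"line {lineno}: EST TSV needs 7 fields")
            try:
                align = GenomicInterval(
                    fields[1], int(fields[2]), int(fields[3]),
                    fields[4] if fields[4] in ("+", "-") else ".",  # type: ignore[arg-type]
                    fields[0],
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            tissues = frozenset(t for t in fields[6].split(";") if t.strip())
            records.append(EstRecord(fields[0], align, fields[5], tissues))
    return records


def write_est_table(ests: Iterable[EstRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(EST_TSV_COLUMNS) + "\n")
        for est in ests:
            handle.write(
                "\t".join(
                    [
                        est.id,
                        est.align.chrom,
                        str(est.align.start),
                        str(est.align.end),
                        est.align.strand,
                        est.library_id,
                        ";".join(sorted(est.tissues)),
                    ]
                )
                + "\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a UCSC-style two-column chrom.sizes TSV into ``{chrom: length}``."""
    sizes: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"line {lineno}: chrom.sizes needs 2 columns")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer length") from exc
            if length <= 0:
                raise FormatError(f"line {lineno}: chromosome length must be > 0")
            sizes[fields[0]] = length
    return sizes
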