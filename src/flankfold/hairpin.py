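"""Hairpin secondary structures, normalized free energy, candidate filtering.

A candidate locus is a simple, unbranched RNA hairpin described by a
dot-bracket string and its minimum free energy (MFE, kcal/mol). Because raw
MFE scales with length, candidates are compared on normalized free energy
(NFE, kcal/mol/nt): MFE divided by a nucleotide count. Three divisors are
supported:

``all``
    every nucleotide in the window;
``span``
    first paired base through last paired base inclusive (single-stranded
    tails excluded);
``duplex``
    the span minus the terminal loop — only tails and the terminal loop are
    excluded, so internal loops and bulges still count toward the divisor.

The ``duplex`` variant separates genuine miRNA hairpins from spontaneous
genomic hairpins best and is the default; the retention cutoff is
NFE <= -0.44 kcal/mol/nt (inclusive).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .intervals import GenomicInterval, Strand

__all__ = [
    "HairpinStructure",
    "StructureRegions",
    "HairpinPrediction",
    "parse_structure",
    "nfe",
    "filter_hairpins",
    "parse_rnalfold_output",
    "expand_strandless",
    "read_hairpin_table",
    "write_hairpin_table",
    "NFE_CUTOFF",
]

NFE_CUTOFF = -0.44  # kcal/mol/nt, retention is nfe <= cutoff (inclusive)

NfeVariant = Literal["all", "span", "duplex"]


class StructureError(ValueError):
    """A dot-bracket string is unbalanced or not a simple hairpin."""


@dataclass(frozen=True)
class StructureRegions:
    """Decomposition of a simple hairpin into tail / span / loop regions."""

    five_tail_len: int
    three_tail_len: int
    span_len: int       # first paired base through last paired base, inclusive
    loop_len: int       # unpaired run enclosed by the innermost base pair
    paired_count: int   # nucleotides participating in base pairs

    @property
    def total_len(self) -> int:
        return self.five_tail_len + self.span_len + self.three_tail_len

    @property
    def duplex_len(self) -> int:
        return self.span_len - self.loop_len


@dataclass(frozen=True)
class HairpinStructure:
    """Dot-bracket structure plus MFE; sequence is optional.

    Only unbranched hairpins are accepted: a structure with two or more
    independent helix closings (a multiloop) is rejected at construction.
    """

    dotbracket: str
    mfe: float
    sequence: str = ""

    def __post_init__(self) -> None:
        parse_structure(self.dotbracket)  # validates; raises StructureError
        if self.sequence and len(self.sequence) != len(self.dotbracket):
            raise ValueError("sequence and dotbracket lengths differ")

    @property
    def regions(self) -> StructureRegions:
        return parse_structure(self.dotbracket)


@dataclass(frozen=True)
class HairpinPrediction:
    """A hairpin candidate anchored to the genome.

    ``nfe`` caches the normalized free energy under the variant the candidate
    was scored with (``duplex`` unless stated otherwise).
    """

    id: str
    locus: GenomicInterval
    structure: HairpinStructure
    source: str = "custom"          # rnalfold | rnaz | illumina | custom
    nfe: float | None = None

    def __post_init__(self) -> None:
        if len(self.locus) != len(self.structure.dotbracket):
            raise ValueError(
                f"{self.id}: locus length {len(self.locus)} != structure "
                f"length {len(self.structure.dotbracket)}"
            )


def parse_structure(dotbracket: str) -> StructureRegions:
    """Decompose a dot-bracket string into hairpin regions.

    Raises :class:`StructureError` for unbalanced brackets, characters
    outside ``(.)``, or branched (multiloop) structures. A structure is a
    simple hairpin iff every ``(`` precedes every ``)``, which permits any
    pattern of bulges and internal loops but exactly one terminal loop.
    """
    if not dotbracket:
        raise StructureError("empty structure")
    bad = set(dotbracket) - set("().")
    if bad:
        raise StructureError(f"invalid structure characters {sorted(bad)!r}")
    depth = 0
    for ch in dotbracket:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise StructureError("unbalanced brackets")
    if depth != 0:
        raise StructureError("unbalanced brackets")
    n_open = dotbracket.count("(")
    if n_open == 0:
        return StructureRegions(len(dotbracket), 0, 0, 0, 0)
    if dotbracket.find("(", dotbracket.find(")")) != -1:
        raise StructureError("not a simple hairpin: branched structure")

    first_open = dotbracket.find("(")
    last_close = dotbracket.rfind(")")
    last_open = dotbracket.rfind("(")
    first_close = dotbracket.find(")")
    span_len = last_close - first_open + 1
    return StructureRegions(
        five_tail_len=first_open,
        three_tail_len=len(dotbracket) - 1 - last_close,
        span_len=span_len,
        loop_len=first_close - last_open - 1,
        paired_count=2 * n_open,
    )


def nfe(structure: HairpinStructure, variant: NfeVariant = "duplex") -> float:
    """Normalized free energy, kcal/mol/nt, under the chosen divisor."""
    regions = structure.regions
    if variant == "all":
        divisor = regions.total_len
    elif variant == "span":
        divisor = regions.span_len
    elif variant == "duplex":
        divisor = regions.duplex_len
    else:
        raise ValueError(f"unknown NFE variant {variant!r}")
    if divisor <= 0:
        raise StructureError(
            f"NFE variant {variant!r} undefined: divisor {divisor} (no base pairs?)"
        )
    return structure.mfe / divisor


def filter_hairpins(
    preds: Sequence[HairpinPrediction],
    nfe_max: float = NFE_CUTOFF,
    min_len: int = 50,
    max_len: int = 180,
    variant: NfeVariant = "duplex",
) -> list[HairpinPrediction]:
    """Retain candidates with NFE <= ``nfe_max`` and an in-range locus length.

    The cutoff is inclusive ("maximum NFE" bounds the value from above).
    Input order is preserved; the operation is idempotent. ``nfe_max > 0``
    is rejected as a sign-convention mistake.
    """
    if nfe_max > 0:
        raise ValueError(f"nfe_max must be <= 0 kcal/mol/nt, got {nfe_max}")
    kept = []
    for p in preds:
        value = p.nfe if p.nfe is not None else nfe(p.structure, variant)
        if value <= nfe_max and min_len <= len(p.locus) <= max_len:
            kept.append(p)
    return kept


_RNALFOLD_LINE = re.compile(
    r"^(?P<db>[().]+)\s+\(\s*(?P<mfe>-?\d+(?:\.\d+)?)\s*\)\s+(?P<pos>\d+)\s*$"
)


def parse_rnalfold_output(
    text: str,
    chrom: str,
    offset: int = 0,
    strand: Strand = "+",
    window_length: int | None = None,
    id_prefix: str = "hp",
    nfe_variant: NfeVariant = "duplex",
) -> list[HairpinPrediction]:
    """Adapt RNALfold-style output (``dotbracket ( MFE) start``) to predictions.

    ``offset`` is the genomic start of the scanned window; local start
    positions are 1-based. For minus-strand scans the local coordinate axis
    runs along the reverse complement, so genomic placement reflects through
    the window: ``start = offset + window_length - local0 - len``, requiring
    ``window_length``. Non-structure lines (sequence, totals) are skipped;
    lines that look structural but fail to parse raise with their line number.
    """
    if strand == "-" and window_length is None:
        raise ValueError("window_length required for minus-strand coordinates")
    preds: list[HairpinPrediction] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith((".", "(")):
            continue  # sequence echo or trailing total-energy line
        m = _RNALFOLD_LINE.match(stripped)
        if m is None:
            raise ValueError(f"line {lineno}: unparseable structure line {line!r}")
        db = m.group("db")
        mfe = float(m.group("mfe"))
        local0 = int(m.group("pos")) - 1
        if strand == "+":
            start = offset + local0
        else:
            assert window_length is not None
            start = offset + window_length - local0 - len(db)
        locus = GenomicInterval(chrom, start, start + len(db), strand)
        structure = HairpinStructure(db, mfe)
        preds.append(
            HairpinPrediction(
                id=f"{id_prefix}{start}",
                locus=locus,
                structure=structure,
                source="rnalfold",
                nfe=nfe(structure, nfe_variant),
            )
        )
    return preds


def expand_strandless(pred: HairpinPrediction) -> list[HairpinPrediction]:
    """Duplicate a strandless prediction onto both strands.

    Conservation-based predictors (RNAz) do not preserve strandedness, so
    their candidates are considered on either strand. Already-stranded
    predictions are returned unchanged as a singleton.
    """
    if pred.locus.stranded:
        return [pred]
    out = []
    for strand in ("+", "-"):
        locus = GenomicInterval(
            pred.locus.chrom, pred.locus.start, pred.locus.end, strand, pred.locus.name
        )
        out.append(
            HairpinPrediction(
                id=f"{pred.id}_{'fwd' if strand == '+' else 'rev'}",
                locus=locus,
                structure=pred.structure,
                source=pred.source,
                nfe=pred.nfe,
            )
        )
    return out


HAIRPIN_TSV_COLUMNS = ["id", "chrom", "start", "end", "strand", "dotbracket", "mfe", "source"]


def read_hairpin_table(path: str | Path, nfe_variant: NfeVariant = "duplex") -> list[HairpinPrediction]:
    """Read the native hairpin TSV (``id chrom start end strand dotbracket mfe source``)."""
    preds: list[HairpinPrediction] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != HAIRPIN_TSV_COLUMNS:
            raise ValueError(f"line 1: expected header {HAIRPIN_TSV_COLUMNS}, got {header}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValueError(f"line {lineno}: hairpin TSV needs 8 fields")
            try:
                locus = GenomicInterval(
                    f[1], int(f[2]), int(f[3]),
                    f[4] if f[4] in ("+", "-") else ".",  # type: ignore[arg-type]
                    f[0],
                )
                structure = HairpinStructure(f[5], float(f[6]))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            preds.append(
                HairpinPrediction(f[0], locus, structure, f[7], nfe(structure, nfe_variant))
            )
    return preds


def write_hairpin_table(preds: Iterable[HairpinPrediction], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(HAIRPIN_TSV_COLUMNS) + "\n")
        for p in preds:
            handle.write(
                "\t".join(
                    [
                        p.id,
                        p.locus.chrom,
                        str(p.locus.start),
                        str(p.locus.end),
                        p.locus.strand,
                        p.structure.dotbracket,
                        repr(p.structure.mfe),
                        p.source,
                    ]
                )
                + "\n"
            )
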