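"""EST support for hairpin candidates and mature fragments; tissue assignment.

A candidate becomes an EST-supported prediction when at least one EST
terminus sits close to its 3' boundary — the genomic trace an oligo-dT
primed cDNA leaves when reverse transcription runs into the upstream edge
of a cleaved hairpin. Distances are signed in transcription orientation
(downstream positive). Hairpin candidates use a 14-nt window; mature-length
fragments, whose parent hairpin extent is unknown, use a 51-nt window (the
mean distance between a mature miRNA's far end and its hairpin's end).

By default the window is symmetric, |d| <= d_max, admitting termini that
intrude slightly into the hairpin; ``downstream_only=True`` restores the
strictly-downstream reading. EST strand is ignored throughout (dbEST
orientations are unreliable); both termini of an EST are eligible
supporters, and each supporter records which end matched so the priming
interpretation can be audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .hairpin import HairpinPrediction, filter_hairpins, NFE_CUTOFF
from .intervals import EstRecord, GenomicInterval, Terminus, est_termini, three_prime_boundary

__all__ = [
    "SupportedPrediction",
    "signed_distance_3p",
    "support_hairpins",
    "support_fragments",
    "assign_tissues",
    "write_support_table",
    "D_MAX_HAIRPIN",
    "D_MAX_FRAGMENT",
]

D_MAX_HAIRPIN = 14   # nt, hairpin 3'-end to EST terminus
D_MAX_FRAGMENT = 51  # nt, mature fragment 3'-end to EST terminus

UNKNOWN_TISSUE = "unknown"


@dataclass
class SupportedPrediction:
    """A candidate together with the EST termini that support it.

    ``supporters`` holds ``(terminus, signed distance d)`` pairs with
    ``|d| <= d_max`` (or ``0 <= d <= d_max`` in downstream-only mode);
    ``tissues`` is the union of the supporters' tissue labels, with
    label-less supporters contributing ``"unknown"``.
    """

    prediction: HairpinPrediction | GenomicInterval
    supporters: list[tuple[Terminus, int]]
    tissues: set[str] = field(default_factory=set)

    @property
    def interval(self) -> GenomicInterval:
        if isinstance(self.prediction, HairpinPrediction):
            return self.prediction.locus
        return self.prediction

    @property
    def id(self) -> str:
        if isinstance(self.prediction, HairpinPrediction):
            return self.prediction.id
        return self.prediction.name

    @property
    def min_abs_distance(self) -> int:
        return min(abs(d) for _, d in self.supporters)


def signed_distance_3p(iv: GenomicInterval, terminus_position: int) -> int:
    """Signed distance from the interval's 3' boundary to a terminus.

    Positive downstream of the 3' end in transcription direction, negative
    inside/upstream, zero exactly at the boundary.
    """
    boundary = three_prime_boundary(iv)
    if iv.strand == "+":
        return terminus_position - boundary
    return boundary - terminus_position


def _supporters_for(
    iv: GenomicInterval,
    termini: Sequence[Terminus],
    positions: np.ndarray,
    d_max: int,
    downstream_only: bool,
) -> list[tuple[Terminus, int]]:
    boundary = three_prime_boundary(iv)
    lo = np.searchsorted(positions, boundary - d_max, side="left")
    hi = np.searchsorted(positions, boundary + d_max, side="right")
    found = []
    for k in range(int(lo), int(hi)):
        term = termini[k]
        d = signed_distance_3p(iv, term.position)
        if abs(d) > d_max:
            continue
        if downstream_only and d < 0:
            continue
        found.append((term, d))
    return found


def _termini_index(
    ests: Sequence[EstRecord],
) -> dict[str, tuple[list[Terminus], np.ndarray]]:
    by_chrom: dict[str, list[Terminus]] = {}
    for est in ests:
        for term in est_termini(est):
            by_chrom.setdefault(est.align.chrom, []).append(term)
    out = {}
    for chrom, terms in by_chrom.items():
        terms.sort(key=lambda t: t.position)
        out[chrom] = (terms, np.asarray([t.position for t in terms], dtype=np.int64))
    return out


def _support(
    intervals: Sequence[tuple[HairpinPrediction | GenomicInterval, GenomicInterval]],
    ests: Sequence[EstRecord],
    d_max: int,
    downstream_only: bool,
) -> list[SupportedPrediction]:
    if d_max < 0:
        raise ValueError(f"d_max must be >= 0, got {d_max}")
    index = _termini_index(ests)
    supported = []
    for obj, iv in intervals:
        entry = index.get(iv.chrom)
        if entry is None:
            continue
        terms, positions = entry
        found = _supporters_for(iv, terms, positions, d_max, downstream_only)
        if found:
            sp = SupportedPrediction(obj, found)
            _populate_tissues(sp)
            supported.append(sp)
    return supported


def support_hairpins(
    preds: Sequence[HairpinPrediction],
    ests: Sequence[EstRecord],
    d_max: int = D_MAX_HAIRPIN,
    require_nfe: bool = True,
    nfe_max: float = NFE_CUTOFF,
    downstream_only: bool = False,
) -> list[SupportedPrediction]:
    """EST-supported subset of hairpin candidates.

    When ``require_nfe`` is set, candidates are first put through the NFE
    filter (cutoff ``nfe_max``, inclusive; length limits are not re-applied
    here). A candidate is retained when at least one EST terminus lies
    within ``d_max`` of its 3' boundary.
    """
    if require_nfe:
        preds = [p for p in preds if p.nfe is not None and p.nfe <= nfe_max]
    return _support([(p, p.locus) for p in preds], ests, d_max, downstream_only)


def support_fragments(
    frags: Sequence[GenomicInterval],
    ests: Sequence[EstRecord],
    d_max: int = D_MAX_FRAGMENT,
    downstream_only: bool = False,
) -> list[SupportedPrediction]:
    """EST-supported subset of mature-length sequencing fragments.

    Fragments approximate mature miRNAs, not hairpins, so the distance is
    measured from the fragment's own 3' boundary with the wider window that
    absorbs the unknown extent of the parent hairpin.
    """
    return _support([(f, f) for f in frags], ests, d_max, downstream_only)


def _populate_tissues(sp: SupportedPrediction) -> None:
    tissues: set[str] = set()
    for term, _ in sp.supporters:
        if term.est.tissues:
            tissues.update(term.est.tissues)
        else:
            tissues.add(UNKNOWN_TISSUE)
    sp.tissues = tissues


def assign_tissues(
    supported: Sequence[SupportedPrediction],
    est_table: Sequence[EstRecord] | None = None,
) -> list[SupportedPrediction]:
    """(Re)populate tissue labels from supporters' library metadata.

    ``est_table``, when given, supplies richer metadata keyed by EST id for
    supporters that were read without tissue labels. Labels are the union
    over supporters; a supporter without any label contributes ``"unknown"``.
    """
    lookup = {e.id: e.tissues for e in est_table} if est_table is not None else {}
    for sp in supported:
        tissues: set[str] = set()
        for term, _ in sp.supporters:
            labels = term.est.tissues or lookup.get(term.est.id, frozenset())
            if labels:
                tissues.update(labels)
            else:
                tissues.add(UNKNOWN_TISSUE)
        sp.tissues = tissues
    return list(supported)


def tissue_counts(supported: Sequence[SupportedPrediction]) -> dict[str, int]:
    """Number of supported predictions per tissue label (one per label hit)."""
    counts: dict[str, int] = {}
    for sp in supported:
        for t in sorted(sp.tissues):
            counts[t] = counts.get(t, 0) + 1
    return counts


def write_support_table(
    supported: Sequence[SupportedPrediction], path: str | Path
) -> None:
    with open(path, "w") as handle:
        handle.write(
            "pred_id\tchrom\tstart\tend\tstrand\tnfe\t"
            "n_supporting_ests\tmin_abs_distance\ttissues\n"
        )
        for sp in supported:
            iv = sp.interval
            nfe_val = (
                f"{sp.prediction.nfe:.4f}"
                if isinstance(sp.prediction, HairpinPrediction) and sp.prediction.nfe is not None
                else "NA"
            )
            n_ests = len({t.est.id for t, _ in sp.supporters})
            handle.write(
                f"{sp.id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{nfe_val}\t{n_ests}\t{sp.min_abs_distance}\t"
                f"{';'.join(sorted(sp.tissues))}\n"
            )
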