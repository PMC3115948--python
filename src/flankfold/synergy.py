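"""Multiplicative combination of per-miRNA target scores.

TargetScan-style context scores are negative numbers where more-negative
means stronger predicted repression. To rank transcripts for *synergistic*
repression by a fixed set of miRNAs, the per-miRNA scores are combined
multiplicatively — the ranking key is the product of their absolute values.
A transcript whose score for any one miRNA is near zero is pushed down the
ranking no matter how strong the others are, which is exactly the behaviour
wanted for co-targeting: one weak site vetoes the synergy claim.

Scores must be <= 0; transcripts missing a score for a required miRNA are
excluded (taking the veto to its limit) rather than imputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["SynergyRow", "combine_and_rank", "top_k", "read_score_table", "write_ranked_table"]


@dataclass
class SynergyRow:
    """One transcript with its per-miRNA context scores."""

    transcript_id: str
    scores: dict[str, float]
    description: str = ""
    combined_magnitude: float = 0.0
    rank: int = 0


def combine_and_rank(
    rows: Sequence[SynergyRow] | Sequence[Mapping],
    required_mirnas: Sequence[str],
) -> list[SynergyRow]:
    """Rank transcripts by the product of absolute context scores.

    Every retained row must carry a score for every required miRNA; rows
    with a missing score are dropped with a warning. A positive score is a
    sign-convention error and raises. Ties are broken by transcript id
    (lexicographic), so ranks are unique and reproducible.
    """
    if not required_mirnas:
        raise ValueError("required_mirnas must be non-empty")
    kept: list[SynergyRow] = []
    for row in rows:
        if not isinstance(row, SynergyRow):
            row = SynergyRow(
                transcript_id=row["transcript_id"],
                scores={m: row[m] for m in required_mirnas if m in row and row[m] is not None},
                description=row.get("description", ""),
            )
        missing = [
            m for m in required_mirnas
            if m not in row.scores or row.scores[m] is None or math.isnan(row.scores[m])
        ]
        if missing:
            warnings.warn(
                f"{row.transcript_id}: missing score for {missing}; row excluded",
                stacklevel=2,
            )
            continue
        for m in required_mirnas:
            if row.scores[m] > 0:
                raise ValueError(
                    f"{row.transcript_id}: positive context score "
                    f"{row.scores[m]} for {m}; scores must be <= 0"
                )
        row.combined_magnitude = math.prod(abs(row.scores[m]) for m in required_mirnas)
        kept.append(row)
    kept.sort(key=lambda r: (-r.combined_magnitude, r.transcript_id))
    for i, row in enumerate(kept, start=1):
        row.rank = i
    return kept


def top_k(ranked: Sequence[SynergyRow], k: int) -> list[SynergyRow]:
    """Stable prefix of the ranking; warns when fewer than k rows exist."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranked):
        warnings.warn(f"requested top {k} but only {len(ranked)} rows", stacklevel=2)
    return list(ranked[:k])


def read_score_table(path: str | Path, required_mirnas: Sequence[str]) -> list[SynergyRow]:
    """Read a score TSV: ``transcript_id  description  <one column per miRNA>``."""
    df = pd.read_csv(path, sep="\t")
    if "transcript_id" not in df.columns:
        raise ValueError("score table needs a transcript_id column")
    missing = [m for m in required_mirnas if m not in df.columns]
    if missing:
        raise ValueError(f"score table lacks columns for {missing}")
    rows = []
    for rec in df.to_dict("records"):
        rows.append(
            SynergyRow(
                transcript_id=str(rec["transcript_id"]),
                scores={m: rec[m] for m in required_mirnas if pd.notna(rec.get(m))},
                description=str(rec.get("description", "") or ""),
            )
        )
    return rows


def write_ranked_table(
    ranked: Sequence[SynergyRow], required_mirnas: Sequence[str], path: str | Path
) -> None:
    records = [
        {
            "transcript_id": r.transcript_id,
            "description": r.description,
            **{m: r.scores[m] for m in required_mirnas},
            "combined_magnitude": round(r.combined_magnitude, 6),
            "rank": r.rank,
        }
        for r in ranked
    ]
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)
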