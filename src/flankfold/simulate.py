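"""Synthetic toy genomes with planted hairpin/EST/fragment structure.

The generator emulates the statistical situation the EST-flank method
assumes, so every pipeline stage can be exercised without downloads:

* *true loci* — planted miRNA-like hairpins (fully paired arms around a
  terminal loop) whose duplex NFE is drawn below the -0.44 kcal/mol/nt
  retention cutoff, each carrying a nested mature interval placed by the
  empirical d1/d2 laws (short/long mature-to-hairpin end distances,
  means 12.7 and 51.3 nt);
* *decoy loci* — hairpins whose NFE law sits on the weak side of the
  cutoff, mimicking spontaneously arising genomic hairpins;
* *ESTs* — for each expressed true locus, oligo-dT-style reads whose
  upstream terminus falls just downstream of the hairpin 3' end (offset
  uniform on 0..14 nt by default), over a uniform background of unrelated
  ESTs; supporting ESTs inherit the locus' tissue label;
* *fragments* — one mature-length (21 nt) read per expressed locus at the
  planted mature interval, strand randomized, plus uniform noise reads.

Structures are planted with known dot-brackets and assigned MFE values
rather than folded: the pipeline consumes (structure, MFE) pairs and is
agnostic to their provenance, which keeps every test independent of any
folding engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .hairpin import HairpinPrediction, HairpinStructure
from .intervals import EstRecord, GenomicInterval, MirnaAnnotation

__all__ = [
    "SyntheticConfig",
    "make_genome",
    "simulate_ests",
    "simulate_fragments",
    "truth_predictions",
    "truth_annotations",
    "write_fasta",
]

Law = Callable[[np.random.Generator, int], np.ndarray]


def uniform_int_law(low: int, high: int) -> Law:
    """Uniform integers on the inclusive range [low, high]."""
    def draw(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.integers(low, high + 1, size=n)
    return draw


def poisson_law(mean: float) -> Law:
    def draw(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.poisson(mean, size=n)
    return draw


def truncated_normal_law(
    mean: float, sd: float, lower: float = -np.inf, upper: float = np.inf
) -> Law:
    """Normal(mean, sd) with out-of-bounds draws resampled."""
    def draw(rng: np.random.Generator, n: int) -> np.ndarray:
        out = rng.normal(mean, sd, size=n)
        bad = (out < lower) | (out > upper)
        while bad.any():
            out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            bad = (out < lower) | (out > upper)
        return out
    return draw


@dataclass
class SyntheticConfig:
    """Study conditions for the planted toy genome.

    NFE laws keep true and decoy supports on opposite sides of the -0.44
    retention boundary by construction, so the NFE filter is clean and the
    EST filter's contribution can be measured on top of it. Mature
    placement laws are centred on the empirical 12.7/51.3 nt means so the
    calibration stage recovers the 51-nt fragment cutoff.
    """

    rng_seed: int = 0
    n_chroms: int = 4
    chrom_len: int = 1_000_000
    n_true_loci: int = 50
    n_decoy_loci: int = 5000
    arm_len: int = 22            # decoy arm length, nt
    loop_len: int = 8            # terminal loop, nt (all loci)
    mature_len: int = 21
    est_per_true_locus: Law = field(default_factory=lambda: poisson_law(2.0))
    est_offset_law: Law = field(default_factory=lambda: uniform_int_law(0, 14))
    est_len_law: Law = field(default_factory=lambda: uniform_int_law(200, 600))
    background_est_rate: float = 0.2       # ESTs per kb
    true_nfe_law: Law = field(
        default_factory=lambda: truncated_normal_law(-0.60, 0.05, upper=-0.45)
    )
    decoy_nfe_law: Law = field(
        default_factory=lambda: truncated_normal_law(-0.30, 0.08, lower=-0.44)
    )
    mature_d1_law: Law = field(
        default_factory=lambda: truncated_normal_law(12.7, 5.0, lower=0.0)
    )
    mature_d2_law: Law = field(
        default_factory=lambda: truncated_normal_law(51.3, 15.0, lower=0.0)
    )
    tissue_labels: tuple[str, ...] = (
        "muscle", "myotube", "embryo", "embryonic stem cell", "liver",
    )
    n_noise_fragments: int = 50
    edge_margin: int = 1000      # loci stay this far from chromosome ends
    max_placement_retries: int = 2000

    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_len for i in range(self.n_chroms)}


TRUTH_COLUMNS = [
    "id", "kind", "chrom", "start", "end", "strand", "dotbracket", "mfe",
    "nfe", "mature_start", "mature_end", "tissue",
]


def _place_nonoverlapping(
    rng: np.random.Generator,
    lengths: Sequence[int],
    cfg: SyntheticConfig,
) -> list[tuple[str, int]]:
    """Rejection-sample disjoint (chrom, start) placements for each length."""
    import bisect

    starts_by_chrom: dict[str, list[int]] = {c: [] for c in cfg.chrom_sizes()}
    ends_by_chrom: dict[str, list[int]] = {c: [] for c in cfg.chrom_sizes()}
    chroms = list(starts_by_chrom)
    placements = []
    for length in lengths:
        for _ in range(cfg.max_placement_retries):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            lo = cfg.edge_margin
            hi = cfg.chrom_len - cfg.edge_margin - length
            if hi <= lo:
                raise ValueError("chromosome too short for locus + margins")
            start = int(rng.integers(lo, hi + 1))
            end = start + length
            starts = starts_by_chrom[chrom]
            ends = ends_by_chrom[chrom]
            i = bisect.bisect_left(starts, end)
            # overlap only possible with the interval just before insertion point
            if i > 0 and ends[i - 1] > start:
                continue
            starts.insert(i, start)
            ends.insert(i, end)
            placements.append((chrom, start))
            break
        else:
            raise RuntimeError(
                "could not place loci without overlap; genome too crowded"
            )
    return placements


def make_genome(cfg: SyntheticConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Build the toy genome: chromosome sequences plus the truth table.

    True loci get geometry from the mature-placement laws: the hairpin is
    mature + d1 + d2 nucleotides long (parity absorbed into the longer
    distance), with which end carries the shorter distance randomized.
    Decoys use the fixed ``arm_len``/``loop_len`` geometry. MFE values are
    assigned so the configured duplex-NFE law holds exactly.
    """
    rng = np.random.default_rng([cfg.rng_seed, 0])
    n_true, n_decoy = cfg.n_true_loci, cfg.n_decoy_loci

    # --- true locus geometry from the placement laws ---
    draws_a = cfg.mature_d1_law(rng, n_true)
    draws_b = cfg.mature_d2_law(rng, n_true)
    d_short = np.minimum(draws_a, draws_b).round().astype(int)
    d_long = np.maximum(draws_a, draws_b).round().astype(int)
    lengths_true = []
    arms_true = []
    loops_true = []
    for ds, dl in zip(d_short, d_long):
        total = cfg.mature_len + int(ds) + int(dl)
        # absorb arm-parity into the loop so planted distances stay exact
        loop = cfg.loop_len + ((total - cfg.loop_len) % 2)
        arm = (total - loop) // 2
        lengths_true.append(total)
        arms_true.append(arm)
        loops_true.append(loop)

    decoy_len = 2 * cfg.arm_len + cfg.loop_len
    lengths = lengths_true + [decoy_len] * n_decoy
    placements = _place_nonoverlapping(rng, lengths, cfg)

    true_nfe = cfg.true_nfe_law(rng, n_true)
    decoy_nfe = cfg.decoy_nfe_law(rng, n_decoy)
    strands = np.where(rng.random(n_true + n_decoy) < 0.5, "+", "-")
    short_at_5p = rng.random(n_true) < 0.5

    rows = []
    for i in range(n_true):
        chrom, start = placements[i]
        length, arm, loop = lengths_true[i], arms_true[i], loops_true[i]
        end = start + length
        strand = strands[i]
        ds, dl = int(d_short[i]), int(d_long[i])
        d5 = ds if short_at_5p[i] else dl       # transcription-5' distance
        # genomic mature placement: 5' distance is from start on +, end on -
        if strand == "+":
            m_start = start + d5
        else:
            m_start = end - d5 - cfg.mature_len
        duplex_len = 2 * arm
        nfe_val = float(true_nfe[i])
        rows.append(
            {
                "id": f"true{i:04d}",
                "kind": "true",
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "dotbracket": "(" * arm + "." * loop + ")" * arm,
                "mfe": nfe_val * duplex_len,
                "nfe": nfe_val,
                "mature_start": m_start,
                "mature_end": m_start + cfg.mature_len,
                "tissue": cfg.tissue_labels[i % len(cfg.tissue_labels)],
            }
        )
    decoy_db = "(" * cfg.arm_len + "." * cfg.loop_len + ")" * cfg.arm_len
    for j in range(n_decoy):
        chrom, start = placements[n_true + j]
        nfe_val = float(decoy_nfe[j])
        rows.append(
            {
                "id": f"decoy{j:05d}",
                "kind": "decoy",
                "chrom": chrom,
                "start": start,
                "end": start + decoy_len,
                "strand": strands[n_true + j],
                "dotbracket": decoy_db,
                "mfe": nfe_val * (2 * cfg.arm_len),
                "nfe": nfe_val,
                "mature_start": pd.NA,
                "mature_end": pd.NA,
                "tissue": "",
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)

    # --- sequences: random background, hairpin arms planted in place ---
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    genome: dict[str, np.ndarray] = {
        c: alphabet[rng.integers(0, 4, size=cfg.chrom_len)]
        for c in cfg.chrom_sizes()
    }
    for row in rows:
        arm = row["dotbracket"].count("(")
        loop = len(row["dotbracket"]) - 2 * arm
        arm_seq = alphabet[rng.integers(0, 4, size=arm)]
        loop_seq = alphabet[rng.integers(0, 4, size=loop)]
        rc = np.array(
            [complement[b.decode()].encode() for b in arm_seq[::-1]], dtype="S1"
        )
        genome[row["chrom"]][row["start"]: row["end"]] = np.concatenate(
            [arm_seq, loop_seq, rc]
        )
    sequences = {c: arr.tobytes().decode() for c, arr in genome.items()}
    return sequences, truth


def simulate_ests(
    truth: pd.DataFrame, cfg: SyntheticConfig
) -> tuple[list[EstRecord], dict[str, int]]:
    """Plant supporting ESTs downstream of expressed true loci over background.

    Returns the EST records and the per-true-locus supporting-EST count (a
    locus with count 0 is unexpressed and unrecoverable by design). Each
    supporting EST's near terminus sits at ``3' boundary + offset`` with the
    offset drawn from ``est_offset_law``; the read extends 200-600 nt
    further downstream. Background ESTs are uniform at
    ``background_est_rate`` per kb with random tissue labels.
    """
    rng = np.random.default_rng([cfg.rng_seed, 1])
    ests: list[EstRecord] = []
    counts: dict[str, int] = {}
    true_rows = truth[truth["kind"] == "true"]
    n_draws = cfg.est_per_true_locus(rng, len(true_rows))
    k = 0
    for (_, row), n_est in zip(true_rows.iterrows(), n_draws):
        counts[row["id"]] = int(n_est)
        if n_est == 0:
            continue
        offsets = cfg.est_offset_law(rng, int(n_est))
        lens = cfg.est_len_law(rng, int(n_est))
        for off, length in zip(offsets, lens):
            off, length = int(off), int(length)
            if row["strand"] == "+":
                start = row["end"] + off
                end = start + length
            else:
                end = row["start"] - off
                start = end - length
            start = max(0, start)
            end = min(cfg.chrom_len, end)
            ests.append(
                EstRecord(
                    id=f"est_s{k:05d}",
                    align=GenomicInterval(row["chrom"], start, end, "."),
                    library_id=f"lib_{row['tissue'].replace(' ', '_')}",
                    tissues=frozenset({row["tissue"]}),
                )
            )
            k += 1
    n_background = int(round(cfg.background_est_rate * cfg.n_chroms * cfg.chrom_len / 1000))
    chroms = list(cfg.chrom_sizes())
    bg_lens = cfg.est_len_law(rng, n_background)
    for b in range(n_background):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(bg_lens[b])
        start = int(rng.integers(0, cfg.chrom_len - length + 1))
        tissue = cfg.tissue_labels[int(rng.integers(0, len(cfg.tissue_labels)))]
        ests.append(
            EstRecord(
                id=f"est_b{b:05d}",
                align=GenomicInterval(chrom, start, start + length, "."),
                library_id=f"lib_{tissue.replace(' ', '_')}",
                tissues=frozenset({tissue}),
            )
        )
    return ests, counts


def simulate_fragments(
    truth: pd.DataFrame,
    cfg: SyntheticConfig,
    est_counts: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Mature-length sequencing fragments at planted mature sites plus noise.

    One fragment per true locus (restricted to expressed loci when
    ``est_counts`` is given), placed exactly at the planted mature interval
    with randomized strand — mirroring the loss of strand information in
    small-RNA library prep. Noise fragments are uniform 21-mers.
    """
    rng = np.random.default_rng([cfg.rng_seed, 2])
    frags: list[GenomicInterval] = []
    true_rows = truth[truth["kind"] == "true"]
    for _, row in true_rows.iterrows():
        if est_counts is not None and est_counts.get(row["id"], 0) == 0:
            continue
        if pd.isna(row["mature_start"]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        frags.append(
            GenomicInterval(
                row["chrom"], int(row["mature_start"]), int(row["mature_end"]),
                strand, f"frag_{row['id']}",
            )
        )
    chroms = list(cfg.chrom_sizes())
    for j in range(cfg.n_noise_fragments):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, cfg.chrom_len - cfg.mature_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frags.append(
            GenomicInterval(chrom, start, start + cfg.mature_len, strand, f"noise{j:04d}")
        )
    return frags


def truth_predictions(truth: pd.DataFrame) -> list[HairpinPrediction]:
    """All planted loci (true + decoy) as hairpin candidates with duplex NFE."""
    preds = []
    for _, row in truth.iterrows():
        structure = HairpinStructure(row["dotbracket"], float(row["mfe"]))
        preds.append(
            HairpinPrediction(
                id=row["id"],
                locus=GenomicInterval(
                    row["chrom"], int(row["start"]), int(row["end"]),
                    row["strand"], row["id"],
                ),
                structure=structure,
                source="custom",
                nfe=float(row["nfe"]),
            )
        )
    return preds


def truth_annotations(truth: pd.DataFrame) -> list[MirnaAnnotation]:
    """True loci as known-miRNA annotations (hairpin + nested mature)."""
    anns = []
    for _, row in truth[truth["kind"] == "true"].iterrows():
        locus = GenomicInterval(
            row["chrom"], int(row["start"]), int(row["end"]), row["strand"], row["id"]
        )
        matures: tuple[GenomicInterval, ...] = ()
        if not pd.isna(row["mature_start"]):
            matures = (
                GenomicInterval(
                    row["chrom"], int(row["mature_start"]), int(row["mature_end"]),
                    row["strand"], f"{row['id']}_mature",
                ),
            )
        anns.append(MirnaAnnotation(row["id"], locus, matures))
    return anns


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sequences.items()]
    seqio_write(records, str(path), "fasta")
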