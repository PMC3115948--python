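"""Decompose hairpin structures, compute NFE variants, filter candidates.

A candidate pre-miRNA is a dot-bracket structure plus its minimum free
energy (MFE). Raw MFE scales with length, so candidates are compared on
normalized free energy (NFE = MFE / nucleotide count) with three possible
divisors; the `duplex` divisor (paired span minus the terminal loop) is the
default, with retention at NFE <= -0.44 kcal/mol/nt.
"""

from flankfold import HairpinStructure, filter_hairpins, nfe, parse_structure
from flankfold.hairpin import HairpinPrediction
from flankfold.intervals import GenomicInterval

db = "..((((....)))).."
regions = parse_structure(db)
print(f"structure {db}")
print(
    f"  5' tail {regions.five_tail_len} nt, span {regions.span_len} nt, "
    f"terminal loop {regions.loop_len} nt, 3' tail {regions.three_tail_len} nt, "
    f"{regions.paired_count} paired nt"
)

s = HairpinStructure(db, mfe=-4.8)
for variant in ("all", "span", "duplex"):
    print(f"  NFE ({variant:6s}) = {nfe(s, variant):+.3f} kcal/mol/nt")
# The divisor shrinks from 16 to 12 to 8 nt, so |NFE| grows: the duplex
# variant concentrates the stability signal in the base-paired stem.

candidates = []
for pid, nfe_val in [("strong", -0.61), ("borderline", -0.44), ("weak", -0.30)]:
    arm, loop = 26, 8
    locus = GenomicInterval("chr1", 10_000, 10_000 + 2 * arm + loop, "+", pid)
    structure = HairpinStructure("(" * arm + "." * loop + ")" * arm, nfe_val * 2 * arm)
    candidates.append(HairpinPrediction(pid, locus, structure, nfe=nfe_val))

kept = filter_hairpins(candidates)
print(f"retained at NFE <= -0.44: {[p.id for p in kept]}")
# 'borderline' survives: the cutoff is inclusive ("maximum NFE" bounds from above).
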