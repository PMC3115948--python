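"""Published mouse-genome reference numbers used as worked-example inputs.

These small tables are *inputs*, not results: the genome-scale screens they
summarize (millions of RNALfold hairpins against the 2007 dbEST snapshot)
are far beyond what ships with a library, but their printed counts let the
arithmetic layers — precision/recall bookkeeping, S/N ratios, synergy
ranking — be exercised and checked end to end on real numbers.
"""

from __future__ import annotations

from .benchmark import BenchmarkCounts

# ---------------------------------------------------------------------------
# mm9 prediction benchmark: A/B/C/D counts per predictor, with and without
# EST integration. Keys: (predictor, with_ests).
# ---------------------------------------------------------------------------
MM9_BENCHMARK_COUNTS: dict[tuple[str, bool], BenchmarkCounts] = {
    ("illumina", False): BenchmarkCounts(3446, 3446, 348, 463),
    ("illumina", True): BenchmarkCounts(3446, 540, 108, 132),
    ("rnalfold", False): BenchmarkCounts(3340947, 3340947, 393, 463),
    ("rnalfold", True): BenchmarkCounts(3340947, 40782, 81, 91),
    ("rnaz", False): BenchmarkCounts(62057, 62057, 144, 463),
    ("rnaz", True): BenchmarkCounts(62057, 12617, 35, 91),
}

# ---------------------------------------------------------------------------
# EST-intersection enrichment at 14 nt: observed count and within-chromosome
# shuffle-null mean, per genome assembly and predictor.
# ---------------------------------------------------------------------------
ENRICHMENT_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("mm8", "rnalfold"): (41347, 33182),
    ("mm8", "rnaz"): (17245, 4176),
    ("mm8", "illumina"): (112, 25),
    ("mm9", "rnalfold"): (40872, 32496),
    ("mm9", "rnaz"): (12617, 3039),
    ("mm9", "illumina"): (88, 18),
}

# ---------------------------------------------------------------------------
# TargetScan context scores for the top 10 transcripts co-targeted by the
# three miRNAs upregulated in differentiating myoblasts.
# ---------------------------------------------------------------------------
MYOGENIC_MIRNAS = ("mir-24", "mir-26a", "mir-351")

MYOGENIC_TARGET_SCORES: list[dict] = [
    {"transcript_id": "Plod2", "mir-24": -0.3234, "mir-26a": -0.7219, "mir-351": -0.2086,
     "description": "Procollagen-lysine,2-oxoglutarate 5-dioxygenase 2 Precursor"},
    {"transcript_id": "Dmd", "mir-24": -0.352, "mir-26a": -0.2867, "mir-351": -0.4483,
     "description": "Dystrophin"},
    {"transcript_id": "Tbc1d30", "mir-24": -0.4755, "mir-26a": -0.5532, "mir-351": -0.1713,
     "description": "TBC1 domain family member 30"},
    {"transcript_id": "Ret", "mir-24": -0.3827, "mir-26a": -0.5018, "mir-351": -0.1895,
     "description": "Proto-oncogene tyrosine-protein kinase receptor ret Precursor"},
    {"transcript_id": "4732454E20Rik", "mir-24": -0.7775, "mir-26a": -0.3364, "mir-351": -0.1225,
     "description": "Protein FAM26D"},
    {"transcript_id": "Irf4", "mir-24": -0.1166, "mir-26a": -0.516, "mir-351": -0.5252,
     "description": "Interferon regulatory factor 4"},
    {"transcript_id": "Papola", "mir-24": -0.5424, "mir-26a": -0.229, "mir-351": -0.2491,
     "description": "Poly(A) polymerase alpha"},
    {"transcript_id": "Zfp697", "mir-24": -0.492, "mir-26a": -0.3602, "mir-351": -0.1722,
     "description": "Zinc finger protein 697"},
    {"transcript_id": "Slc25a35", "mir-24": -0.3222, "mir-26a": -0.2178, "mir-351": -0.4084,
     "description": "Solute carrier family 25 member 35"},
    {"transcript_id": "St8sia4", "mir-24": -0.3275, "mir-26a": -0.335, "mir-351": -0.2319,
     "description": "CMP-N-acetylneuraminate-poly-alpha-2,8-sialyltransferase"},
]
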