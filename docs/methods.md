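# Methods

## The model

miRNA genes are excised from longer, polyadenylated primary transcripts by
Drosha/DGCR8 cleavage. The 3′ fragment left behind keeps its poly-A tail,
so oligo-dT-primed reverse transcription — the standard chemistry of EST
library construction — can capture it, and the resulting cDNA ends where
the polymerase ran into the cleavage site. Aligned to the genome, such an
EST has a terminus immediately downstream of the hairpin's 3′ end. The
package treats that terminus as orthogonal evidence of cleavage and uses it
to filter structural hairpin predictions, which by themselves are
hopelessly unspecific at genome scale.

Assumptions worth stating explicitly:

* the candidate is a *simple, unbranched* hairpin (one terminal loop;
  multiloops are rejected, not trimmed);
* EST alignment orientation is unreliable (dbEST mixes strands), so both
  endpoints of every EST are candidate termini and EST strand is ignored by
  default;
* coordinates are 0-based half-open throughout; "boundary" means the
  position between bases, so all distances are exact integer differences.

## Normalized free energy

NFE = MFE / *n* (kcal/mol/nt). Three divisors *n* are supported:

| variant  | divisor                                              |
|----------|------------------------------------------------------|
| `all`    | full window length                                   |
| `span`   | first paired base through last paired base inclusive |
| `duplex` | span minus the terminal loop (default)               |

Internal loops and bulges *count* toward the `span` and `duplex` divisors;
only the single-stranded tails and the terminal loop are excluded from
`duplex`. Retention is NFE ≤ −0.44 kcal/mol/nt, *inclusive*: "maximum NFE"
bounds the value from above and the boundary case is kept. Because MFE ≤ 0
and the divisor shrinks from `all` to `duplex`, |NFE(all)| ≤ |NFE(span)| ≤
|NFE(duplex)| always holds (a property test asserts it).

## EST support

A hairpin is EST-supported when at least one terminus satisfies
|d| ≤ `d_max` where d is the signed distance from the hairpin's 3′ boundary
(downstream positive in transcription orientation). Defaults:

* `d_max = 14` nt for hairpin candidates;
* `d_max = 51` nt for mature-length sequencing fragments, whose parent
  hairpin extent is unknown: 51 is the rounded mean of d₂, the longer of
  the two mature-to-hairpin end distances measured over annotated
  mature/pre-miRNA pairs (means ≈ 12.7 and 51.3 nt).

The window is symmetric by design: the method description covers both a
"downstream terminus" reading and termini "within the structure", and a
symmetric |d| ≤ 14 honors both; `downstream_only=True` restores the strict
reading (0 ≤ d ≤ d_max). How far a terminus may intrude before it
contradicts mature-miRNA generation is not quantified anywhere we could
anchor it, so the symmetric window is an interpretation, kept configurable.

Tissue assignment is the union of the supporters' library tissue labels
(case-insensitive exact strings, no ontology mapping); a supporter with no
label contributes `unknown`.

## Occupancy profiles and the central-peak bootstrap

For each feature, a window of ±`half_width` (default 1000 nt, i.e. a 2-kb
window) is centered on the 3′ (or 5′) boundary; offsets are flipped on the
minus strand so downstream is always positive. Each terminus in a window
scores 1/*n*, where *n* counts *termini* in that window — not EST records —
so each occupied window contributes exactly unit mass and the invariant
*total mass = number of occupied windows* holds exactly (asserted in
tests). The per-record reading would break that conservation whenever both
ends of one EST fall in a window. Scores aggregate over features into
10-nt bins.

The test statistic is the **central peak**: the larger of the two bins
flanking offset 0. The observed peak sits immediately adjacent to the
anchored end under the cleavage model, but the statistic's support is a
design choice and is configurable. The null shuffles the *whole feature
set jointly* per replicate to uniform random same-chromosome,
same-strand-preserving locations (one interpretation of the published
procedure; the alternative — one window at a time — has the same marginal
null). The empirical P counts replicates with statistic ≥ observed and is
reported as `k/R`, or `<1/R` when k = 0; with the default R = 10,000 a
saturated signal prints `<0.0001`. Replicate RNG streams are derived from
one seed by counter (`default_rng([seed, replicate])`), so results are
reproducible and parallelizable. A fast path computes only the two central
bins per replicate; a regression test pins it to the full profile.

The enrichment variant of the same bootstrap counts *candidates with ≥1
terminus within d_max* instead of bin mass, and reports S/N = observed /
null mean (rounded to 2 decimals).

## Benchmarking

Counts follow the A/B/C/D scheme: A raw candidates, B candidates surviving
the EST filter (B = A without EST data), C unique known miRNAs detected, D
knowns predictable under the active evidence regime (all knowns without
EST data; with EST data, knowns with a terminus within d_max of their 3′
end in structure mode, or knowns containing ≥1 raw fragment in fragment
mode). Precision = 100·C/B, recall = 100·C/D, rounded half-up to two
decimals — the convention under which the published mm9 percentage cells
reproduce exactly from their printed counts.

Detection rules: structure mode requires *reciprocal* overlap ≥ 75% (both
fractions; a single-sided mode exists behind a flag), fragment mode
requires the fragment to lie wholly inside the known locus on either
strand (fragment strandedness is generally unrecoverable from small-RNA
libraries). The calibration grid sweeps NFE cutoffs (0 to −1) × distance
cutoffs (0 to 200 nt) and uses a stricter 80% overlap by default,
mirroring the stricter threshold used for grid calibration; "unique
miRNAs" always counts distinct known IDs, never prediction objects.

Mature-placement statistics measure, per mature-in-hairpin pair, the
5′-to-5′ and 3′-to-3′ boundary distances; d₁ = min, d₂ = max, and the
derived fragment cutoff is mean(d₂) rounded half-down (51.3 → 51).

## Synthetic data: what it does and does not emulate

The generator plants, on 4 × 1 Mb chromosomes by default:

* **50 true loci**: fully-paired arms around an 8-nt loop, length set to
  21 + d₁ + d₂ with d₁ ~ N(12.7, 5) and d₂ ~ N(51.3, 15) (truncated ≥ 0;
  arm parity is absorbed into the loop so the planted distances are exact);
  duplex NFE ~ N(−0.60, 0.05) truncated ≤ −0.45; a 21-nt mature nested at
  the drawn distances, shorter distance on a random end; a tissue label
  assigned round-robin.
* **5000 decoys**: fixed 52-nt geometry, NFE ~ N(−0.30, 0.08) truncated
  ≥ −0.44 — spontaneous hairpins on the weak side of the cutoff.
* **ESTs**: per true locus, Poisson(2) supporting reads (a locus drawing 0
  is unexpressed and unrecoverable by design) whose near terminus sits at
  3′ boundary + U{0..14} and which extend 200–600 nt downstream; plus 0.2
  background ESTs per kb, uniform, with random tissues.
* **Fragments**: the planted mature interval per expressed locus, strand
  randomized, plus 50 uniform noise 21-mers.

MFE values are *assigned* to match the NFE laws rather than folded: the
pipeline consumes (structure, MFE) pairs and is agnostic to their
provenance, which keeps all tests independent of any folding engine.

Deliberately not emulated: sequence composition realism (no k-mer
matching), conservation signal for comparative predictors, EST splicing,
chained/overlapping transcription units, assembly differences. Passing
tests therefore demonstrate the correctness and calibration of the
*machinery* — not that real dbEST data are as clean as the planted signal;
on real data the true/decoy NFE distributions overlap and EST backgrounds
are structured, so real precision gains are the published tens-fold, not
the ~100-fold seen on the separated synthetic laws.

## Numerical and design choices

* NFE cutoff comparison is `<=` (inclusive); `nfe_max > 0` is rejected as a
  sign mistake.
* Percentage rounding is half-up, 2 decimals (`decimal` arithmetic, no
  float-tie surprises); the d₂ cutoff rounds half-down, matching 51.3 → 51.
* Branched structures raise rather than being trimmed to their largest
  stem: the model's object is a simple hairpin, and silent trimming would
  change the NFE divisor.
* Default hairpin length window is 50–180 nt; the upstream folding window
  semantics belong to the external folding tool. Both bounds are exposed
  because no canonical values are fixed by the method description.
* Empirical P-values use k/R (not (k+1)/(R+1)); ties count as exceedances,
  which is mildly conservative. Calibration under a uniform null is
  verified empirically (rejection rate at nominal 5% within binomial 99%
  bounds over 200 datasets at R = 200).
* Problem sizes in tests and the acceptance script (4 Mb genome, 5050
  candidates, R = 200–500 bootstrap replicates, 200 calibration datasets,
  n = 500 placement pairs) were chosen so the full suite runs in seconds
  while keeping every stochastic check inside its stated statistical
  tolerance; all are configurable upward.

## Known limitations

* No pri-miRNA transcript reconstruction or EST splice-graph analysis: a
  terminus is a point, not a transcript model.
* The EST-strand-agnostic default can admit antisense coincidences; the
  strict same-strand mode exists but was not the default because EST
  orientation metadata is unreliable in practice.
* The RNALfold adapter parses the common `structure ( energy ) position`
  dialect only; other folding-tool outputs should be converted to the
  native hairpin TSV.
* Genome-scale published counts (millions of hairpins against millions of
  ESTs) are inputs to the arithmetic layers here, not recomputed: they
  require the original genome assemblies and a frozen 2007 dbEST snapshot.
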