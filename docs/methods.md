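# Methods

## Model and procedure

The pipeline compares two pooled DNA samples drawn from the phenotypic
extremes of a diversity panel. Under the pooling model, a locus causal for
(or tightly linked to) the contrasting trait is near-fixed for opposite
alleles in the two pools, while the rest of the genome shares allele
frequencies between pools up to binomial sampling noise. The analysis chain
is:

1. **Hard filtering** of the joint-called VCF: biallelic sites only, both
   pools genotyped, per-pool depth DP ≥ 15 and genotype quality GQ ≥ 20.
   Removal reasons are tallied with a fixed precedence (multiallelic →
   missing genotype → DP → GQ → optional site-annotation filters), so a
   record is counted once and raw = survivors + Σ removals.
2. **Allele-frequency estimation**: per pool,
   `AFe = alt / (ref + alt)` over *informative* reads — reads assigned to
   either allele — rather than the DP field, which may count reads
   supporting neither. Sites with zero informative reads in a pool are
   skipped and logged. `delta = |AFe_a − AFe_b|`.
3. **Coverage band**: a site is kept when each pool's informative depth
   lies within `[0.75·mean, 2.5·mean]` of that pool's own mean depth
   (bounds inclusive; mean estimated over the post-filter record set unless
   supplied). The lower bound removes noisy sparse sites; the upper bound
   removes collapsed-repeat pileups whose apparent allele frequencies are
   chimeric.
4. **Interval detection**: see below.

## Interval detection

Let the *matching pool* be the one whose phenotype matches the reference
assembly, so causal sites appear there as runs of near-zero AFe. A site
*qualifies* when its matching-pool AFe ≤ `run_max_afe` (0.1, inclusive). A
*seed* is a qualifying site with `delta ≥ X`, where

    X = P − 100·E/C

with pool phenotypic difference `P` (0.9), sequencing-error rate `E`
(0.01) and combined informative coverage `C`. X is the divergence one
would still observe at a truly fixed-different locus after `E·C` error
reads; applying it per site permits a small number of non-supportive reads
at low coverage without loosening the rule where coverage is high. Setting
`E = 0` disables the adjustment (flat `delta ≥ P` seeding). The
qualifying rule and X are combined conjunctively at the seed — a
documented interpretation of two under-specified requirements (near-zero
matching AFe; error-adjusted divergence); the conjunction reproduces the
intent of both and is the stricter reading.

From each seed, extension proceeds left and right through consecutive
qualifying sites. A block of at most `max_interruption` (default 1)
consecutive non-qualifying sites is absorbed iff qualifying sites flank it
on both sides; a longer block terminates extension at the last qualifying
site. Interruption tolerance is counted in variants, not bases. Extensions
from different seeds that overlap merge (they provably reach identical
endpoints, so merging is a formality); intervals with fewer than
`min_variants` (default 2 — an interval needs two marker loci) qualifying
members are discarded. The interval spans first to last *member* site:
marker-to-marker, with no extension to midpoints between flanking
non-members. Absorbed interrupters lie inside the span but are not
members. Chromosomes are processed independently, and when a stitch
liftover table is supplied, sites on a super-scaffold are partitioned by
source scaffold so no interval spans an N-spacer gap.

Within a detected interval, the variant report lists sites with
`delta ≥ delta_report_threshold` (0.9). The upstream description of this
report filter ("AFe ≥ 0.9") is ambiguous about which quantity is
thresholded; delta is used here, consistent with delta ≥ 0.9 denoting
homozygote dissimilarity.

A brute-force reference detector (`enumerate_intervals_bruteforce`)
enumerates every qualifying start/end pair, checks the interruption
constraint with precomputed prefix structures, keeps runs containing a
seed and enough members, and discards runs contained in larger valid runs.
It shares no code path with the seed-extension detector and is compared
against it exactly in the tests and the acceptance script.

Detection assigns no statistical confidence to intervals; significance
testing, gene prediction and annotation are out of scope.

## Pool construction

Chemotype fractions are computed from the eight cannabinoid fresh-weight
concentrations; dicyclic = (CBDVA+CBDA+CBDV+CBD)/total, C3-alkyl =
(CBDVA+THCVA+CBDV+THCV)/total, with tricyclic and C5-alkyl their
complements. Plants with zero total are excluded (logged) since fractions
are undefined; replicate rows are averaged per plant before computation.

How to rank "extreme on both axes" jointly is genuinely open
(threshold-then-rank vs composite). The package uses a composite rank —
`rank(dicyclic, desc) + rank(c3_alkyl, asc)` for the reference-matching
pool, the reverse for the other — with ties broken lexicographically by
plant id. This is deterministic, threshold-free, and nested in k (growing
a pool never evicts a member). The second pool is ranked after excluding
the first pool's members, making disjointness unconditional even in
degenerate all-tied panels. Selectivity = 100·k/n is reported to one
decimal; internal values keep full precision.

## Scaffold stitching

Unplaced scaffolds are concatenated with runs of exactly 550 N (default)
into super-scaffolds; the liftover table stores each source's 0-based
offset. Coordinates are 1-based inclusive internally (VCF convention); BED
exports are 0-based half-open. Absent an explicit plan, all ids not
matching a configurable chromosome pattern are concatenated in input order
(one batch by default) — input order is deterministic and any grouping
yields a valid liftover table. Spacer positions lift to a sentinel, never
to a source coordinate.

## Synthetic data

The generator emulates the data regime of a two-pool extreme-phenotype
resequencing experiment; defaults are the study conditions used
throughout the tests:

| parameter | default | meaning |
|---|---|---|
| `variant_rate` | 1/200 per bp | candidate polymorphic sites |
| `mean_depth` | 55 reads/pool | mid-50s–60s pool coverage |
| `error_rate` E | 0.01 | Illumina-scale per-read error |
| `background_fixed_weight` | 0.6 | share of candidate sites fixed-reference |
| `depth_model` | poisson | per-site depth; `constant` available |
| `indel_fraction` | 0.1 | length-changing alternative alleles |

Background sites share one true alternative-allele frequency `p` between
pools (fixed-reference majority plus Uniform(0,1) segregating sites —
pools drawn from one population agree in expectation); causal-region sites
are fixed-different (`p = 0` matching pool, `p = 1` other). Reads are
binomial: `alt ~ Binomial(d, p(1−E) + (1−p)E)` at depth
`d ~ Poisson(mean)`. GQ is a deterministic saturating function of depth
capped at 99 — enough to exercise the GQ filter without a genotype-
likelihood model — with optional forced low-GQ and missing-genotype sites.
Collapsed-paralog loci are planted via per-region depth multipliers to
exercise the coverage band's upper bound.

**Caller emulation.** By default a site is emitted only when at least one
pool's called genotype (a naive frequency call: hom-ref < 0.25 ≤ het ≤
0.75 < hom-alt) is non-reference. A joint variant caller never reports
sites at which both samples are confidently homozygous reference, and
emitting them would surround causal regions with qualifying (AFe ≈ E)
non-variant sites that no real VCF contains, dragging interval bounds far
outside the causal region. `emit_monomorphic=True` restores every
candidate site (used when checking binomial concentration of AFe around
truth without ascertainment bias).

What the generator does **not** model: read-level artefacts (mapping
error, duplicates, base-quality structure), linkage disequilibrium,
genotype-likelihood-based GQ, multi-allelic sites, and real genome
sequence. Passing closed-loop tests therefore demonstrates correctness of
the estimation and detection logic under the stated sampling model, not
robustness to alignment artefacts in real data.

The chemotype generator draws the dicyclic fraction from a tripartite
low/intermediate/high Beta mixture (weights 0.2/0.2/0.6) and the C3-alkyl
fraction from a low-skewed Beta with an 8% high-C3 minority, emulating a
hemp-dominated panel with a varin-rich subset. Planted extremes draw from
narrow joint ranges typical of real extreme pools (high-dicyclic pool:
dicyclic 94.3–97.1%, C3 0.5–0.9%; high-C3 pool: C3 64.6–92.9%, dicyclic
0.1–2.5%). Concentrations are back-calculated via the exact factorisation
of the eight analytes into (di/tri-cyclic) × (C3/C5-alkyl) ×
(acid/neutral), so `compute_fractions` inverts the draw to 1e-9.

## Numerical and design notes

- DP/GQ thresholds apply per pool (both must pass); "genotyped in both
  pools" is required. All filter boundaries are inclusive on the passing
  side (DP 15 passes, 14 fails; band bounds 0.75× and 2.5× pass).
- The coverage band defaults to per-pool means (stricter and symmetric);
  a combined-coverage mode is provided since either reading of "the
  average depth of coverage" is defensible.
- Site-annotation hard filters (e.g. QD, FS) are an optional configurable
  stage; records lacking an annotation are not failed by it.
- A qualifying site has matching-pool AFe ≤ 0.1 *inclusive*; any
  non-qualifying site counts as an interruption (the interrupting
  variant's "AFe ≥ 0.1" is treated as "> 0.1", resolving the boundary
  consistently with the run rule).
- Tie-breaks everywhere are deterministic (lexicographic plant ids;
  coordinate order for intervals); re-running any stage with the same
  inputs and seed is byte-identical, which the pipeline manifest verifies
  via SHA-256 checksums.
- Problem sizes in tests and the acceptance script (10 × 1 Mb recovery
  genome, 100 random oracle instances ≤ 500 sites, 10,000-profile
  partition check) were chosen as the smallest sizes at which the
  binomial noise regime and run-structure statistics are representative.

## Known limitations

- AFe is a point estimate; no shrinkage or smoothing (e.g. windowed
  G-statistics) is applied, matching the descriptive design.
- The interruption rule tolerates isolated interlopers only; dense
  heterozygous contamination inside a causal region fragments intervals.
- Pool selection assumes two phenotype axes; traits needing more axes
  require a custom ranking.
- The simulator's uniform variant placement understates clustering of
  real polymorphism; interval-length statistics on synthetic data are not
  comparable to real genomes.
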