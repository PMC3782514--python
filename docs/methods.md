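# Methods

This document records the models, default parameters, and numerical choices
behind each `syntevol` module, plus known limitations. All coordinates
throughout the package are 0-based, half-open (`[start, end)`); GFF3 files on
disk use the standard 1-based inclusive convention and are converted at the
I/O boundary.

## Sequence model and coordinates (`regions`)

`GenomicRegion` holds an uppercase DNA sequence (`ACGTN` alphabet; other
IUPAC letters are mapped to `N` with a warning) and a list of
`FeatureInterval`s validated against the sequence bounds. Features may nest
(e.g. `LTR5`/`LTR3` inside a `TE`). FASTA, GFF3 and BED readers/writers
round-trip through this representation; BED carries only
name/start/end/strand, so feature kinds and attributes do not survive a BED
round trip (use GFF3 when they matter).

## Conserved-block detection (`blocks`)

A seed-and-extend detector tuned for closely related (K ≲ 0.2) homologous
regions:

1. **Seeding.** Exact k-mer matches with `k = word_size // 2` (default 20),
   encoded base-4 into int64 codes; k-mers occurring more than
   `max_kmer_occurrences = 16` times in either sequence are dropped as
   repeats. `N` never matches anything.
2. **Diagonal runs.** Seeds are grouped by diagonal (`a_pos - b_pos`) and
   chained into candidate runs wherever a sliding window of `word_size`
   (default 40) columns reaches `min_identity` (default 0.60).
3. **Boundary extension.** Each run is extended outward with a
   maximal-scoring (X-drop-style) rule: match +1, mismatch −1, boundary
   placed at the maximum cumulative score, bounded by the passing-window
   run. This places block edges at the last position where conserved signal
   outweighs noise rather than at the first mismatch.
4. **Merge and overlap resolution.** Runs on the same diagonal closer than
   `merge_distance = 200` bp merge. Blocks overlapping a higher-scoring block
   on either axis are *trimmed* back to the non-overlapping remainder (and
   dropped only if the remainder falls below `min_block_length = 200` bp), so
   a few bp of overlap never discards kilobases of genuine conservation.

**Statistics.** For blocks covering `c` bp of an overlap of `o` bp in `n`
blocks: `CSR = round(100·c/o, 1)` percent and `CFS = floor(c/n)` bp.
`stats_from_totals` applies the same arithmetic to externally supplied
totals. Rounding is "round-half-even to one decimal" for CSR; published
tables of this kind sometimes truncate instead, so a row can differ by 0.1
from an independently computed value.

**Gap classification.** Intervals between consecutive blocks present on
exactly one side (≥ 50 bp, the other side < 50 bp) are classified as:
`TE_insertion` when ≥ 50% covered by an annotated TE; `low_complexity` when
the gap's dinucleotide entropy is low; `deletion` (on the *other* side) when
the gap sequence aligns to a supplied outgroup; otherwise `unknown_indel`.

## CNS detection (`cns`)

Conserved non-coding sequences are detected between *shared anchor genes*:
for each pair of regions and each inter-anchor stretch, the stretches are
globally aligned; alignment columns are marked conserved when they belong to
at least one `window = 100` column span at ≥ `min_identity = 0.80` matching
columns (union of passing windows via a difference array, so conserved runs
are maximal covered-column intervals, not window start positions). Runs ≥
`min_length = 100` bp are projected to reference coordinates, intersected
across all pairs, masked against annotated genic features (`gene`, `exon`,
`CDS`, UTRs, with optional padding), and reported with the *minimum*
pairwise identity across the region set.

Cis-regulatory elements are exact IUPAC consensus matches on both strands
from a PlantCARE-style default table (TATA-box, CAAT-box, GC-box, G-box,
P-box, Py-rich, SP1, MBS); palindromic consensi are reported once. SSRs are
maximal perfect tandem repeats of 1–6 bp primitive units (minimum copies
10/6/5/5/5/5 for unit lengths 1–6), reported under the lexicographically
smallest rotation of the unit.

## Molecular evolution (`molevol`)

**K2P.** With transition proportion `P` and transversion proportion `Q` over
ungapped, non-`N` columns, `K = −½ln(1 − 2P − Q) − ¼ln(1 − 2Q)`.
Arguments of the logarithms must be positive; otherwise a `SaturationError`
is raised. Note this guard can never trigger on data simulated under the
package's own K2P process with finite K — the expected identity stays
strictly above 25% — so it matters only for real or adversarial input.

**NG86 Ka/Ks.** Synonymous site fractions per codon count a position as
synonymous iff a nucleotide change preserves the amino acid and does not
create a stop (stop-adjacent changes count as nonsynonymous sites). For
codons differing at 2–3 positions, substitutions are attributed by averaging
over all substitution orderings, equally weighted, excluding orderings that
pass through a stop codon (falling back to all orderings when every path is
blocked). Proportions `ps = Sd/S`, `pn = Nd/N` are Jukes–Cantor corrected:
`K = −¾ln(1 − 4p/3)`. `omega = Ka/Ks` is `None` when `Ks = 0`. Alignments
shorter than 100 codons trigger a noise warning; terminal stop codons are
stripped and gapped columns dropped before counting; an internal stop is an
error that names the offending codon index.

**Alignment.** `global_align` is Needleman–Wunsch (match +2, mismatch −2,
gap −3) used for stretch/gap alignment; it is adequate for the ≥ 60%
identity regime the detectors operate in, not for remote homology.

## Dating (`dating`)

All dating uses the strict molecular clock `T = K / (2r)`. Presets:
`LTR_RATE = 1.3e-8` and `GRASS_ADH_RATE = 6.5e-9` substitutions/site/year
(the LTR rate is conventionally twice the adh rate). A `Calibration(K_cal,
T_cal)` defines a rate `r = K_cal / (2 T_cal)` from a known divergence.
`ltr_insertion_age` dates a retroelement from the K2P divergence of its twin
LTRs (identical at insertion time). `locus_dating_row` combines two genes:
the slower gene contributes the mean of its coding and intron K (averaged at
full precision before conversion), the faster gene its Ks, each converted
through its own calibration, and the two times averaged.

## Phylogenetics (`phylo`)

Saitou–Nei neighbor joining with lexicographic tie-breaking on the Q-matrix
(deterministic output), three-point formulas for the final 3-node star, and
clamping of negative branch lengths to zero (counted in
`negative_branches_clamped`). On additive matrices NJ recovers the generating
topology exactly. Bootstrap support resamples alignment columns with
replacement, rebuilds K2P/NJ trees, and reports the percentage of replicates
containing each internal bipartition.

## Simulator (`simulate`)

The generator produces homologous regions with exact recoverable truth:

- **Neutral divergence** uses exact per-site K2P marginals (no event-count
  approximation): for branch length `t`, with transition rate α and
  transversion rate β chosen to match the configured ts/tv ratio, each site
  independently carries a transition with probability
  `¼ + ¼e^{−4βt} − ½e^{−2(α+β)t}` and each of the two possible transversions
  with the complementary probability. Estimated K is therefore unbiased by
  construction.
- **LTR elements** insert with identical LTRs; each LTR accumulates
  substitutions at rate `r` for the configured age, so expected twin
  divergence is `2rT`.
- **Genes** evolve by a Gillespie codon process (synonymous rate equal to
  the codon's NG86 synonymous site count, nonsynonymous rate
  `omega · (3 − s_c)`), with internal stops unreachable by construction.
- **`simulate_cds_pair`** (the standalone coding-pair generator used for
  estimator benchmarking) instead *places* substitutions to be
  NG86-consistent in expectation: targets are converted to per-site
  difference proportions by inverting the JC correction, and each codon
  receives at most one single-position change (synonymous with probability
  `ps·s_c`, nonsynonymous with `pn·(3 − s_c)`), applied to a random one of
  the two copies. Single-position codon differences are counted by NG86
  without pathway ambiguity, so the estimator recovers the targets
  unbiasedly. A Gillespie pair generator, by contrast, yields ~+7% upward
  bias in omega at Ks = 0.3 because the JC correction under-corrects
  synonymous multiple hits at two-fold degenerate sites — that is a property
  of the NG86 estimator, not of the data.
- **Indels, SSRs, motifs** are placed at configured loci; the truth object
  records conserved intervals, TE/gene/SSR/motif coordinates per lineage,
  and the expected divergences.

Scope: the generator emulates desk-scale (tens of kb) slices of homologous
grass genome regions. It does not model recombination, gene conversion,
segmental duplication, translocation/inversion, rate heterogeneity across
sites, or base-composition bias.

## Pipeline (`pipeline`, `cli`)

`run_pipeline` takes a validated YAML/dict config (unknown keys rejected at
every level), either simulates lineages or loads FASTA+GFF3 inputs, and
writes TSV tables (conservation summary, gap events, CNS, motifs, SSRs,
gene rates, calibrated clock, LTR ages), BED tracks, a Newick tree, and a
`manifest.json` with SHA-256 checksums of every output. A stage failure
raises `RuntimeError` naming the stage. Identical configs and seeds produce
byte-identical outputs. The `syntevol` console script is a thin `click`
layer over the library.

## Limitations

- The block detector assumes colinearity; inversions or translocations
  break diagonals and will fragment or miss blocks.
- NG86 is a counting method: at Ks ≳ 0.75 proportions saturate
  (`ps ≥ 0.75` raises), and even below saturation omega from process-based
  (Gillespie) data carries the known upward bias described above.
- The clock conversions assume rate constancy; calibrated times inherit the
  calibration's uncertainty, which is not propagated.
- `global_align` is O(n·m) memory; stretches beyond a few tens of kb should
  be pre-split (the pipeline's anchor-gene decomposition does this).
- Bootstrap support is topology-only; branch lengths on the support tree
  come from the full data, not replicate averages.
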