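# Methods

`spotquant` processes reads from a spatially barcoded RNA-seq array — a
printed grid of ~100 µm spots whose capture probes carry a spot-specific DNA
barcode, a semi-randomized unique molecular identifier (UMI) and an oligo-dT
capture sequence — into a spot × gene matrix of unique molecules, and then
quantifies how reproducible replicate tissue sections are. This note records
the model behind each stage, the defaults and why they were chosen, what the
synthetic data does and does not emulate, and the numerical conventions used
throughout.

## Read structure

Each read pair consists of a short forward read and a longer reverse read
(defaults 36 bp and 121 bp). The forward read holds the spot barcode
followed by the UMI; any bases after the UMI (poly-T in practice) carry no
information and are ignored. The reverse read is the transcript fragment.
Barcode and UMI lengths are not dictated by the chemistry itself, only their
sum is bounded by the forward-read length; we default to an 18 bp barcode and
a 9 bp UMI with IUPAC pattern `WSNNWSNNV` (a "semi-random" design that avoids
homopolymer UMIs), all configurable. All sequence intervals are 0-based
half-open; array coordinates are 0-based integer grid indices.

## Reverse-read processing

**Quality trimming** uses the BWA `-q` rule: scanning from the 3′ end, the
running sum of `(q_threshold − q_i)` is evaluated at every cut point and the
read is cut where the sum is maximal (ties resolved toward the longest
retained prefix; untouched when the maximum is ≤ 0). Default threshold
Q20, minimum retained length 25 nt. This rule is monotone: raising the
threshold never lengthens the retained read.

**Ribosomal screening** flags a read when it shares at least `min_shared`
distinct k-mers (default 2, k = 15) with any single ribosomal reference
sequence; both strands of the reference are indexed. At these defaults a
single chance 16 bp match is sufficient to flag a read, which is intended —
rRNA contamination is abundant and cheap to discard — but it means the
synthetic reference must not contain chance gene/rRNA k-mer collisions (see
below).

**Mapping** is a transcriptome k-mer seed-and-extend: reads sample every
5th 15-mer (plus the terminal one), genes collecting ≥ 2 seed hits on either
strand are scored by the ungapped match count on their most-supported
diagonal, and candidates are returned in score order with ties retained.
There is no splicing and no indel handling: the reference is a transcript
set, so gene-assignment semantics are preserved without genomic alignment.
The mapper sits behind a small interface so externally produced alignments
could be substituted.

**Gene assignment** takes the mapper's candidates: none → `unmapped`; a tie
at the top score → `ambiguous` (discarded, the union-mode convention for
multi-gene hits); a unique top hit is `assigned` unless its gene is not
annotated as polyadenylated (`not_polyA`) — only poly-A transcripts can be
captured by oligo-dT probes, so only they are counted. Together with
`too_short` (forward read shorter than barcode + UMI, or reverse read below
the post-trim minimum) and `ribosomal`, the six statuses are mutually
exclusive and exhaustive; the pipeline asserts on every run that their
counters sum to the number of input pairs.

## Spot demultiplexing and UMI collapse

Assigned reads are joined to the (barcode, UMI) parsed from their forward
mates. Barcodes are matched exactly against the array design by default;
a bounded-mismatch mode (up to Hamming distance 2) resolves to the unique
nearest design barcode and discards ties at the minimum distance. The
default of zero mismatches is the strict reading of barcode *filtering*;
tolerance is offered but off.

Duplicate removal is exact: the count for (spot, gene) is the number of
distinct UMI strings observed there, i.e. the number of distinct
(spot, gene, UMI) triples. Exact-string collapse is the minimal faithful
interpretation of UMI deduplication; a directional-network collapse that
merges sequencing-error UMIs is a noted extension point, not implemented.
Dedup is idempotent, order-invariant, and bounded above by the annotated
read count.

## Saturation curves

Library complexity is estimated by down-sampling the annotated reads
(without replacement) to predefined depths and counting unique triples at
each depth; the default grid is 10 evenly spaced depths up to the full
count. Each replicate draws one permutation and takes nested prefixes, so
every replicate's curve is monotone non-decreasing by construction, and the
per-depth mean over replicates is reported with its standard deviation.
The estimator has a closed form used as a test oracle: with N reads and
molecule m covered by c_m duplicates, the expected unique count at depth d
is Σ_m [1 − C(N−c_m, d)/C(N, d)], evaluated in log-gamma space. A paired
raw-FASTQ down-sampler (same record indices applied to both mates) mirrors
depth equalization across libraries before processing.

## Replicate statistics

Sections are compared in bulk (per-gene counts summed over all spots) or
within a selected region (per-gene counts averaged over the region's spots,
zeros included in the denominator — the "average spot" of, e.g., a ten-spot
inflamed area). Sample vectors are depth-normalized with the
median-of-ratios size-factor estimator: s_j is the median over genes —
restricted to genes nonzero in every sample — of count_gj divided by the
gene's geometric mean across samples. The estimator is implemented from
this definition rather than calling an external package; an independent
reference implementation is used as a cross-check in the tests. Normalized
counts are transformed as log2(x + 1) and compared by pairwise Pearson
correlation over the full shared gene universe (no detected-gene filtering);
group summaries are arithmetic means of the off-diagonal correlations.
Region comparisons follow the declared order: average → normalize → log2 →
correlate, treating the region pseudo-spots as their own sample group.
Dispersion of scalar replicate quantities is summarized as the coefficient
of variation, 100 × sd(n−1)/mean.

## Synthetic data

The generator emulates what the pipeline must undo, with defaults chosen as
the study conditions for all tests:

- **Array**: grid design with unique random barcodes; 1007 spots by default
  (the printed-array format this pipeline targets), small grids in tests.
- **Transcriptome**: random transcripts of 300–1500 nt, 80% flagged
  polyadenylated (the rest exercise the annotation filter), plus 2 rRNA
  sequences of 1500 nt. rRNA candidates are redrawn until they share no
  15-mer (either strand) with any gene: with fully random short sequences a
  chance 16 bp gene/rRNA match occurs at an appreciable rate and would make
  the screen discard legitimate mRNA reads — an artifact of the toy genome
  scale that real ribosomal RNA does not present.
- **Expression**: one lognormal baseline mean per gene (spread σ = 0.5,
  mean-preserving around 10 molecules/spot/gene), constant across spots; a
  contiguous block of spots (default 10, the spots nearest a seeded center)
  has a seeded 20% subset of genes scaled by a fold-change (default 4),
  emulating a focal inflamed region shared across replicate sections.
- **Reads**: per (spot, gene), molecule count ~ Poisson(mean); each molecule
  draws a pattern-conforming UMI and emits Geometric(1/dup_mean) read pairs
  (mean 3 — the simplest one-parameter duplication model that creates a
  UMI-collapse workload); fragments start 3′-biased (exponential offset,
  scale 50 nt, modeling oligo-dT priming), carry substitution errors at
  2×10⁻³/base, and with probability 0.1 a scrambled low-quality 3′ tail
  (10–40 nt, qualities 2–8) that the trimmer must remove; 5% of pairs come
  from rRNA and 1% from random sequence; forward reads are error-free
  barcode + UMI + poly-T. Transcripts shorter than the reverse read are
  poly-A padded (polyadenylated genes) or skipped with a warning.
- **Ground truth** records every molecule with its PCR copy count, plus the
  rRNA/noise read counts, and exactly accounts for every emitted pair.

Two deliberate idealizations: UMIs are drawn *without replacement* within
each (spot, gene) pair, so true molecules are never conflated by UMI
collision (with a 9 bp `WSNNWSNNV` pattern the space is 12 288 UMIs, so real
collisions would be rare but nonzero); and spot-to-spot variation comes only
from Poisson sampling, with technical noise modeled as per-gene lognormal
factors at the section level. Consequently, passing the exact-recovery test
shows the pipeline inverts its own generative model perfectly — it does not
bound UMI-collision undercounting, diffusion between spots, indel errors, or
mapping to an intron-containing genome, none of which are simulated.

A count-level shortcut (`simulate_replicate_counts`) draws replicate
sections directly as Poisson counts with per-gene lognormal technical
factors (mean-preserving, σ configurable); it powers the concordance
studies where read-level detail is irrelevant.

## Numerical choices and degenerate inputs

Trimming ties keep the longest read; mapper score ties are never broken
silently (they become `ambiguous`); barcode-distance ties are discarded.
Saturation depths of 0 and N are exact (0 and the distinct-triple count).
The size-factor estimator raises when no gene is nonzero in every sample,
with advice to pseudo-bulk or filter; Pearson correlation raises on
zero-variance vectors, naming the sample; the CV raises on zero mean.
Empty count matrices serialize to a header-only TSV. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; repeated
calls with one seed are byte-identical.

## Problem sizes

The validation suite and the reproduction script run a 50-spot × 100-gene
array at ~50 000 molecules and threefold duplication (~150 000 read pairs
per section), three sections per noise group — sizes at which every stage's
behavior, including the closed-form saturation check at 50–200 replicates,
is measurable on a single CPU in minutes. These are the package's reference
problem sizes; nothing in the implementation is specific to them.

## Known limitations

Exact UMI collapse (no error-tolerant clustering); exact-by-default barcode
matching with no whitelist learning; transcriptome-only ungapped mapping (no
splicing, no indels); no differential-expression testing, dispersion
estimation, batch correction or spot clustering; no extrapolation of
saturation curves beyond the observed depth.
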