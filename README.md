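# spotquant

Processing and reproducibility analysis for spatially barcoded RNA-seq.

Spatial transcriptomics arrays print capture probes in a grid of barcoded
spots: every transcript captured on the tissue carries a spot-specific DNA
barcode (its position on the array) and a unique molecular identifier (UMI,
so PCR copies can be collapsed to one molecule). `spotquant` takes the
resulting paired reads — barcode + UMI on the short forward read, transcript
fragment on the long reverse read — and produces

1. a **spot × gene matrix of unique molecules** (quality trimming → rRNA
   removal → transcriptome mapping → poly-A-only gene assignment → barcode
   demultiplexing → exact UMI deduplication),
2. **saturation curves** (unique molecules recovered vs down-sampled
   sequencing depth, with a closed-form hypergeometric expectation), and
3. **replicate-concordance statistics**: bulk or region-averaged per-gene
   counts, median-of-ratios size-factor normalization, log2(x+1), pairwise
   Pearson correlation matrices and coefficients of variation.

It is aimed at method developers and analysts who need a small, fully
inspectable, desk-scale pipeline for barcoded-array data — including a
synthetic-data generator with complete ground truth, so every stage can be
validated without external data.

## The statistics at the core

- **Unique molecules**: the count for spot s and gene g is the number of
  distinct (s, g, UMI) triples among annotated reads — duplicate reads with
  the same spatial barcode are removed using the UMI.
- **Saturation**: down-sampling d of N annotated reads without replacement,
  a molecule with c duplicate reads is recovered with probability
  1 − C(N−c, d)/C(N, d); the curve of expected unique molecules vs d shows
  whether the library was sequenced to exhaustion.
- **Normalization**: size factor s_j = median over genes (nonzero in all
  samples) of count_gj / geometric-mean_g; counts are divided by s_j, then
  log2(x+1)-transformed before Pearson correlation.
- **Dispersion**: CV = 100 · sd/mean over replicate values.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
from pathlib import Path
import spotquant as sq
from spotquant.config import PipelineConfig
from spotquant.pipeline import layout_from_config, run_pipeline
from spotquant.replicate_stats import (
    bulk_sum, log2_pseudo, normalize_counts, pearson_matrix,
)
from spotquant.saturation import saturation_curve

out = Path("demo"); out.mkdir(exist_ok=True)
cfg = PipelineConfig()

# a 100-spot array, a 50-gene toy transcriptome, and a shared expression
# profile with a 10-spot "inflamed region" at 4-fold expression
design = sq.make_array_design(n_spots=100, n_cols=10, seed=0)
tx = sq.make_transcriptome(n_genes=50, seed=1)
profiles = sq.make_spot_profiles(design, tx, baseline_mean=5.0,
                                 region_effect=4.0, seed=2)

# reads with PCR duplicates, base errors, low-quality tails, 5% rRNA
fwd, rev, truth = sq.simulate_reads(profiles, tx, layout_from_config(cfg),
                                    out / "R1.fastq", out / "R2.fastq", seed=3)
print(f"simulated {truth.n_molecules} molecules -> {truth.total_reads} read pairs")

result = run_pipeline(fwd, rev, design, tx, config=cfg)
print("per-read statuses:", result.status_counts)
print(f"unique molecules: {result.counts.total_molecules}")

keys = [r.molecule_key for r in result.annotated_reads]
curve = saturation_curve(keys, n_replicates=20, seed=4)
for d, u in zip(curve.depths[::3], curve.unique_transcripts[::3]):
    print(f"  depth {d:>6} -> {u:>8.1f} unique")

# a second replicate section from the same profiles
fwd2, rev2, _ = sq.simulate_reads(profiles, tx, layout_from_config(cfg),
                                  out / "B1.fastq", out / "B2.fastq", seed=5)
result2 = run_pipeline(fwd2, rev2, design, tx, config=cfg)
a = bulk_sum(result.counts, "section_1")
b = bulk_sum(result2.counts, "section_2")
r = pearson_matrix(log2_pseudo(normalize_counts([a, b]))).pair("section_1", "section_2")
print(f"between-replicate Pearson r (log2, normalized): {r:.4f}")
```

Output:

```text
simulated 25965 molecules -> 83215 read pairs
per-read statuses: {'too_short': 0, 'ribosomal': 4161, 'unmapped': 832, 'ambiguous': 0, 'not_polyA': 16152, 'assigned': 62070}
unique molecules: 20528
  depth   6207 ->   5163.3 unique
  depth  24828 ->  13731.9 unique
  depth  43449 ->  17988.5 unique
  depth  62070 ->  20528.0 unique
between-replicate Pearson r (log2, normalized): 0.9889
```

Reading the numbers: 25 965 captured molecules were amplified into 83 215
read pairs. The pipeline discarded the rRNA contamination (4 161 reads) and
unmappable noise (832), filtered reads from non-polyadenylated genes
(16 152), and collapsed the 62 070 assigned reads back to 20 528 unique
polyadenylated molecules. The saturation curve flattens toward full depth
— 40% of the reads already recover two-thirds of the molecules — and two replicate
sections of the same tissue profile correlate at r ≈ 0.99 after
normalization.

The same flow is available from the shell:

```sh
spotquant --seed 0 simulate --outdir sim --n-spots 100 --n-genes 50
spotquant process --fwd sim/reads_R1.fastq --rev sim/reads_R2.fastq \
    --design sim/design.tsv --transcriptome sim/transcriptome.fasta \
    --annotation sim/annotation.tsv --rrna sim/rrna.fasta \
    --out-counts counts.tsv --out-assignments assign.tsv
spotquant saturation --assignments assign.tsv --out curve.tsv
spotquant compare counts_a.tsv counts_b.tsv --out-corr corr.tsv \
    --region-file sim/region_spots.txt
```

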