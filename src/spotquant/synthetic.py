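"""Synthetic barcoded-array experiment generator with ground truth.

Emulates what the sequencer sees in a spatially barcoded RNA-seq run: a small
transcriptome (polyadenylated and non-polyadenylated genes plus ribosomal
sequences), per-spot expression with a localized "inflamed region" effect
shared across replicate sections, and paired FASTQ reads carrying

* forward read: spot barcode + semi-randomized UMI + poly-T filler,
* reverse read: a 3'-biased transcript fragment with substitution errors and,
  optionally, a low-quality 3' tail,
* PCR duplication (several reads sharing one UMI), ribosomal contamination and
  unmappable noise reads.

Every emitted molecule is recorded in a :class:`GroundTruth` table so the
downstream pipeline can be tested for exact recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .array_design import IUPAC_CODES, ArrayDesign, ReadLayout

__all__ = [
    "Gene",
    "SyntheticTranscriptome",
    "SpotProfiles",
    "GroundTruth",
    "make_array_design",
    "make_transcriptome",
    "make_spot_profiles",
    "simulate_reads",
    "simulate_replicate_counts",
    "load_transcriptome",
    "load_annotation",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Gene:
    gene_id: str
    seq: str
    polyadenylated: bool


@dataclass(frozen=True)
class SyntheticTranscriptome:
    """A toy transcriptome: genes (with a poly-A flag) plus rRNA sequences."""

    genes: tuple[Gene, ...]
    rrna: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene_ids are not unique")
        if not any(g.polyadenylated for g in self.genes) or all(
            g.polyadenylated for g in self.genes
        ):
            raise ValueError("need at least one polyadenylated and one non-polyA gene")
        for g in self.genes:
            if not g.seq or set(g.seq) - set("ACGT"):
                raise ValueError(f"gene {g.gene_id}: empty or non-ACGT sequence")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def polya_gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes if g.polyadenylated]

    def annotation(self) -> dict[str, bool]:
        """gene_id -> polyadenylated flag."""
        return {g.gene_id: g.polyadenylated for g in self.genes}

    def sequences(self) -> dict[str, str]:
        return {g.gene_id: g.seq for g in self.genes}

    def write_fasta(self, path: str | Path) -> Path:
        recs = [SeqRecord(Seq(g.seq), id=g.gene_id, description="") for g in self.genes]
        SeqIO.write(recs, str(path), "fasta")
        return Path(path)

    def write_rrna_fasta(self, path: str | Path) -> Path:
        recs = [SeqRecord(Seq(s), id=rid, description="") for rid, s in self.rrna]
        SeqIO.write(recs, str(path), "fasta")
        return Path(path)

    def write_annotation(self, path: str | Path) -> Path:
        """GTF-like TSV: gene_id, polyA flag, transcript length."""
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_id\tpolyA\tlength\n")
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{int(g.polyadenylated)}\t{len(g.seq)}\n")
        return path


def load_transcriptome(
    fasta: str | Path, annotation: str | Path, rrna_fasta: Optional[str | Path] = None
) -> SyntheticTranscriptome:
    """Rebuild a transcriptome from FASTA + annotation TSV (+ optional rRNA FASTA)."""
    polya = load_annotation(annotation)
    genes = tuple(
        Gene(rec.id, str(rec.seq).upper(), polya[rec.id])
        for rec in SeqIO.parse(str(fasta), "fasta")
    )
    rrna: tuple[tuple[str, str], ...] = ()
    if rrna_fasta is not None:
        rrna = tuple(
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(rrna_fasta), "fasta")
        )
    return SyntheticTranscriptome(genes, rrna)


def load_annotation(path: str | Path) -> dict[str, bool]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene_id"], df["polyA"].astype(bool)))


@dataclass(frozen=True)
class SpotProfiles:
    """Per-spot mean expression with a designated inflamed-region block.

    ``expression`` is a spots x genes DataFrame of mean molecule counts
    (rows labelled ``"x_y"``); ``region_spots`` lists the coordinates of the
    contiguous inflamed region and ``region_genes`` the genes whose means are
    scaled there by the region effect.
    """

    design: ArrayDesign
    expression: pd.DataFrame
    region_spots: tuple[tuple[int, int], ...]
    region_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.expression.shape[0] != self.design.n_spots:
            raise ValueError("expression rows do not match design spots")
        coords = set(self.design.coordinates)
        for s in self.region_spots:
            if s not in coords:
                raise ValueError(f"region spot {s} not in design")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.columns)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def make_array_design(
    n_spots: int = 1007,
    n_cols: int = 33,
    barcode_length: int = 18,
    umi_length: int = 9,
    umi_pattern: str = "WSNNWSNNV",
    seed: int = 0,
) -> ArrayDesign:
    """Generate a grid array design with unique random barcodes.

    Spots are laid out row-major on an ``n_cols``-wide grid; the 1007-spot
    default mirrors the printed array format the pipeline targets.
    """
    rng = np.random.default_rng(seed)
    barcodes: list[str] = []
    seen: set[str] = set()
    while len(barcodes) < n_spots:
        bc = _random_seq(rng, barcode_length)
        if bc not in seen:
            seen.add(bc)
            barcodes.append(bc)
    spots = tuple(
        (bc, i % n_cols, i // n_cols) for i, bc in enumerate(barcodes)
    )
    return ArrayDesign(spots, umi_length=umi_length, umi_pattern=umi_pattern)


def make_transcriptome(
    n_genes: int = 100,
    length_range: tuple[int, int] = (300, 1500),
    polyA_fraction: float = 0.8,
    n_rrna: int = 2,
    rrna_length: int = 1500,
    seed: int = 0,
) -> SyntheticTranscriptome:
    """Generate random transcript sequences with a poly-A annotation split.

    ``round(n_genes * polyA_fraction)`` genes are flagged polyadenylated; the
    rest exercise the annotation filter downstream.  Deterministic per seed.
    """
    if n_genes < 2:
        raise ValueError("need n_genes >= 2")
    if not 0 < polyA_fraction < 1:
        raise ValueError("polyA_fraction must be in (0, 1)")
    lo, hi = length_range
    if not 0 < lo <= hi:
        raise ValueError(f"degenerate length_range {length_range}")
    rng = np.random.default_rng(seed)
    n_polya = int(round(n_genes * polyA_fraction))
    n_polya = min(max(n_polya, 1), n_genes - 1)
    width = len(str(n_genes - 1))
    genes = []
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        genes.append(
            Gene(f"gene_{i:0{width}d}", _random_seq(rng, length), i < n_polya)
        )
    # rRNA must be distinguishable from mRNA: redraw any candidate sharing a
    # 15-mer (either strand) with a gene, a chance artifact of short random
    # sequences that real ribosomal RNA does not exhibit
    k_screen = 15
    comp = str.maketrans("ACGT", "TGCA")
    gene_kmers = set()
    for g in genes:
        for s in (g.seq, g.seq.translate(comp)[::-1]):
            gene_kmers.update(s[i : i + k_screen] for i in range(len(s) - k_screen + 1))
    rrna = []
    for j in range(n_rrna):
        for _attempt in range(100):
            cand = _random_seq(rng, rrna_length)
            cand_kmers = {
                cand[i : i + k_screen] for i in range(len(cand) - k_screen + 1)
            }
            if not cand_kmers & gene_kmers:
                break
        else:
            raise RuntimeError("could not draw rRNA disjoint from gene k-mers")
        rrna.append((f"rRNA_{j}", cand))
    return SyntheticTranscriptome(tuple(genes), tuple(rrna))


def make_spot_profiles(
    design: ArrayDesign,
    transcriptome: SyntheticTranscriptome,
    baseline_mean: float = 10.0,
    region_effect: float = 4.0,
    region_size: int = 10,
    region_gene_fraction: float = 0.2,
    gene_sigma: float = 0.5,
    seed: int = 0,
) -> SpotProfiles:
    """Build per-spot mean expression with a contiguous inflamed-region block.

    Each gene draws one baseline mean (lognormal spread ``gene_sigma`` around
    ``baseline_mean``, mean-preserving) shared by all spots; a seeded subset of
    genes is scaled by ``region_effect`` inside a contiguous block of
    ``region_size`` spots (the spots nearest a seeded center), emulating a
    focal inflamed region shared across replicate sections.
    """
    if region_size > design.n_spots:
        raise ValueError("region_size exceeds number of spots")
    rng = np.random.default_rng(seed)
    gene_ids = transcriptome.gene_ids
    n_genes = len(gene_ids)
    gene_means = baseline_mean * np.exp(
        gene_sigma * rng.standard_normal(n_genes) - gene_sigma**2 / 2
    )
    expr = np.tile(gene_means, (design.n_spots, 1))

    coords = np.array(design.coordinates, dtype=float)
    center = coords[rng.integers(0, len(coords))]
    dist = np.hypot(coords[:, 0] - center[0], coords[:, 1] - center[1])
    order = np.lexsort((coords[:, 0], coords[:, 1], dist))
    region_idx = order[:region_size]
    n_region_genes = max(1, int(round(region_gene_fraction * n_genes)))
    region_gene_idx = rng.choice(n_genes, size=n_region_genes, replace=False)
    expr[np.ix_(region_idx, region_gene_idx)] *= region_effect

    expression = pd.DataFrame(expr, index=design.spot_labels(), columns=gene_ids)
    region_spots = tuple(
        (int(coords[i, 0]), int(coords[i, 1])) for i in region_idx
    )
    region_genes = tuple(sorted(gene_ids[i] for i in region_gene_idx))
    return SpotProfiles(design, expression, region_spots, region_genes)


@dataclass(frozen=True)
class GroundTruth:
    """True molecule table for a simulated run.

    ``molecules`` holds one row per captured molecule: spot barcode, gene,
    UMI, and the number of PCR copies (read pairs) it emitted.  (spot, gene,
    UMI) triples are unique.  Total emitted read pairs =
    sum(n_pcr_copies) + n_rrna_reads + n_noise_reads.
    """

    molecules: tuple[tuple[str, str, str, int], ...]
    n_rrna_reads: int
    n_noise_reads: int

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def total_reads(self) -> int:
        return int(sum(m[3] for m in self.molecules)) + self.n_rrna_reads + self.n_noise_reads

    def copy_counts(self) -> np.ndarray:
        return np.array([m[3] for m in self.molecules], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.molecules, columns=["barcode", "gene_id", "umi", "n_pcr_copies"]
        )

    def true_matrix(self, design: ArrayDesign, gene_ids: Sequence[str]) -> pd.DataFrame:
        """Spots x genes matrix of true molecule counts on the given gene universe."""
        mat = pd.DataFrame(
            0, index=design.spot_labels(), columns=list(gene_ids), dtype=np.int64
        )
        genes = set(gene_ids)
        for bc, gid, _umi, _c in self.molecules:
            if gid in genes:
                spot = design.spot_of(bc)
                mat.loc[f"{spot[0]}_{spot[1]}", gid] += 1
        return mat

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#n_rrna_reads={self.n_rrna_reads}\n")
            fh.write(f"#n_noise_reads={self.n_noise_reads}\n")
            fh.write("barcode\tgene_id\tumi\tn_pcr_copies\n")
            for bc, gid, umi, c in self.molecules:
                fh.write(f"{bc}\t{gid}\t{umi}\t{c}\n")
        return path

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GroundTruth":
        meta = {}
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    k, v = line[1:].split("=")
                    meta[k] = int(v)
                elif line and not line.startswith("barcode\t"):
                    bc, gid, umi, c = line.split("\t")
                    rows.append((bc, gid, umi, int(c)))
        return cls(tuple(rows), meta["n_rrna_reads"], meta["n_noise_reads"])


def _draw_umi(rng: np.random.Generator, pattern: str) -> str:
    return "".join(
        IUPAC_CODES[c][rng.integers(0, len(IUPAC_CODES[c]))] for c in pattern
    )


def _mutate(rng: np.random.Generator, seq: list[str], positions: np.ndarray) -> None:
    for p in positions:
        old = seq[p]
        choices = [b for b in "ACGT" if b != old]
        seq[p] = choices[rng.integers(0, 3)]


def simulate_reads(
    profiles: SpotProfiles,
    transcriptome: SyntheticTranscriptome,
    layout: ReadLayout,
    fwd_path: str | Path,
    rev_path: str | Path,
    dup_mean: float = 3.0,
    error_rate: float = 0.002,
    tail_lowq_prob: float = 0.1,
    rrna_fraction: float = 0.05,
    noise_fraction: float = 0.01,
    forward_error_rate: float = 0.0,
    q_threshold: int = 20,
    frag_bias_scale: float = 50.0,
    seed: int = 0,
) -> tuple[Path, Path, GroundTruth]:
    """Emit paired FASTQ files (Phred+33) plus the ground-truth molecule table.

    Per spot and gene the molecule count is Poisson with the profile mean.
    Each molecule draws a UMI from the design's IUPAC pattern (distinct within
    its (spot, gene) pair) and emits a geometric number of PCR copies with
    mean ``dup_mean``.  Reverse reads are 3'-biased transcript fragments of
    ``layout.reverse_length`` bases with substitution errors at ``error_rate``
    and, with probability ``tail_lowq_prob``, a scrambled low-quality 3' tail
    (qualities below ``q_threshold``).  ``rrna_fraction`` /
    ``noise_fraction`` of all read pairs come from rRNA sequences / random
    sequence instead of a transcript.  Forward reads are barcode + UMI +
    poly-T filler, error-free unless ``forward_error_rate`` is set.
    Deterministic per seed.
    """
    for name, v in (
        ("error_rate", error_rate),
        ("tail_lowq_prob", tail_lowq_prob),
        ("rrna_fraction", rrna_fraction),
        ("noise_fraction", noise_fraction),
        ("forward_error_rate", forward_error_rate),
    ):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if dup_mean < 1:
        raise ValueError("dup_mean must be >= 1")
    if rrna_fraction + noise_fraction >= 1:
        raise ValueError("rrna_fraction + noise_fraction must be < 1")
    rng = np.random.default_rng(seed)
    design = profiles.design
    rev_len = layout.reverse_length
    seqs = transcriptome.sequences()
    annotation = transcriptome.annotation()

    # effective template per gene: poly-A pad short polyadenylated
    # transcripts; short non-polyA genes cannot be fragmented and are skipped
    templates: dict[str, str] = {}
    for gid, s in seqs.items():
        if len(s) < rev_len:
            if annotation[gid]:
                templates[gid] = s + "A" * (rev_len - len(s))
            else:
                warnings.warn(
                    f"gene {gid}: non-polyA transcript shorter than the reverse "
                    f"read ({len(s)} < {rev_len}); skipped"
                )
        else:
            templates[gid] = s

    barcode_by_label = {f"{x}_{y}": bc for bc, x, y in design.spots}
    molecules: list[tuple[str, str, str, int]] = []
    records: list[tuple[str, str]] = []  # (fwd seq+qual payload deferred below)

    fwd_fill = "T" * (layout.forward_length - layout.min_forward_length)
    fwd_qual = "F" * layout.forward_length  # Q37

    def make_reverse(template: str) -> tuple[str, str]:
        L = len(template)
        delta = int(rng.exponential(frag_bias_scale))
        start = max(0, L - rev_len - delta)
        frag = list(template[start : start + rev_len])
        n = len(frag)
        quals = rng.integers(30, 41, size=n)
        if error_rate > 0:
            n_err = rng.binomial(n, error_rate)
            if n_err:
                _mutate(rng, frag, rng.choice(n, size=n_err, replace=False))
        if tail_lowq_prob > 0 and rng.random() < tail_lowq_prob:
            tail = int(rng.integers(10, min(41, n)))
            quals[n - tail :] = rng.integers(2, max(3, q_threshold - 11), size=tail)
            for p in range(n - tail, n):  # tail bases are garbage calls
                frag[p] = "ACGT"[rng.integers(0, 4)]
        return "".join(frag), "".join(chr(q + 33) for q in quals)

    def make_forward(bc: str, umi: str) -> str:
        f = bc + umi + fwd_fill
        if forward_error_rate > 0:
            n_err = rng.binomial(len(f), forward_error_rate)
            if n_err:
                fl = list(f)
                _mutate(rng, fl, rng.choice(len(f), size=n_err, replace=False))
                f = "".join(fl)
        return f

    pairs: list[tuple[str, str, str]] = []  # (fwd_seq, rev_seq, rev_qual)
    expr = profiles.expression
    for label in expr.index:
        bc = barcode_by_label[label]
        counts = rng.poisson(expr.loc[label].to_numpy())
        for gid, n_mol in zip(expr.columns, counts):
            if n_mol == 0 or gid not in templates:
                continue
            used: set[str] = set()
            for _ in range(int(n_mol)):
                umi = _draw_umi(rng, design.umi_pattern)
                for _attempt in range(1000):
                    if umi not in used:
                        break
                    umi = _draw_umi(rng, design.umi_pattern)
                else:
                    raise RuntimeError("UMI space exhausted for a (spot, gene) pair")
                used.add(umi)
                n_copies = 1 if dup_mean == 1 else int(rng.geometric(1.0 / dup_mean))
                molecules.append((bc, gid, umi, n_copies))
                fwd = make_forward(bc, umi)
                for _c in range(n_copies):
                    rseq, rqual = make_reverse(templates[gid])
                    pairs.append((fwd, rseq, rqual))

    n_signal = len(pairs)
    denom = 1.0 - rrna_fraction - noise_fraction
    total = n_signal / denom if denom > 0 else n_signal
    n_rrna = int(round(rrna_fraction * total)) if transcriptome.rrna else 0
    n_noise = int(round(noise_fraction * total))

    all_barcodes = design.barcodes
    for _ in range(n_rrna):
        rid = int(rng.integers(0, len(transcriptome.rrna)))
        template = transcriptome.rrna[rid][1]
        if len(template) < rev_len:
            template = (template * (rev_len // len(template) + 1))[:rev_len]
        start = int(rng.integers(0, len(template) - rev_len + 1))
        frag = list(template[start : start + rev_len])
        quals = rng.integers(30, 41, size=rev_len)
        if error_rate > 0:
            n_err = rng.binomial(rev_len, error_rate)
            if n_err:
                _mutate(rng, frag, rng.choice(rev_len, size=n_err, replace=False))
        bc = all_barcodes[rng.integers(0, len(all_barcodes))]
        fwd = make_forward(bc, _draw_umi(rng, design.umi_pattern))
        pairs.append((fwd, "".join(frag), "".join(chr(q + 33) for q in quals)))
    for _ in range(n_noise):
        bc = all_barcodes[rng.integers(0, len(all_barcodes))]
        fwd = make_forward(bc, _draw_umi(rng, design.umi_pattern))
        rseq = _random_seq(rng, rev_len)
        rqual = "".join(chr(q + 33) for q in rng.integers(30, 41, size=rev_len))
        pairs.append((fwd, rseq, rqual))

    order = rng.permutation(len(pairs))
    fwd_path, rev_path = Path(fwd_path), Path(rev_path)
    width = max(7, len(str(len(pairs))))
    with open(fwd_path, "w") as ffh, open(rev_path, "w") as rfh:
        for out_i, i in enumerate(order):
            fwd, rseq, rqual = pairs[i]
            rid = f"read_{out_i:0{width}d}"
            ffh.write(f"@{rid}/1\n{fwd}\n+\n{fwd_qual}\n")
            rfh.write(f"@{rid}/2\n{rseq}\n+\n{rqual}\n")

    truth = GroundTruth(tuple(molecules), n_rrna, n_noise)
    assert truth.total_reads == len(pairs)
    return fwd_path, rev_path, truth


def simulate_replicate_counts(
    profiles: SpotProfiles,
    technical_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw one replicate section's spot x gene molecule counts directly.

    Counts are Poisson around the profile means after multiplying each gene by
    a lognormal technical factor exp(sigma*z - sigma^2/2) (mean-preserving);
    ``technical_sigma`` models per-gene library-preparation noise without the
    cost of simulating reads.  Used for replicate-concordance studies.
    """
    rng = np.random.default_rng(seed)
    expr = profiles.expression
    factors = np.exp(
        technical_sigma * rng.standard_normal(expr.shape[1]) - technical_sigma**2 / 2
    )
    lam = expr.to_numpy() * factors
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=expr.index, columns=expr.columns)
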