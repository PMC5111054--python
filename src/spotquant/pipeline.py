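"""End-to-end run: paired FASTQ -> per-read statuses -> spot x gene matrix.

For every read pair the forward read is parsed into (barcode, UMI) and the
reverse read is quality-trimmed, screened against rRNA, mapped to the
transcriptome and resolved to a polyadenylated gene.  Assigned reads whose
barcodes match the array design are collapsed per (spot, gene, UMI) into
unique-molecule counts.  Per-status counters are maintained so that the six
statuses exactly partition the input, and barcode filtering partitions the
assigned class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import zip_longest
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .array_design import ArrayDesign, ReadLayout, parse_forward
from .config import PipelineConfig
from .read_processing import (
    STATUSES,
    RrnaIndex,
    TranscriptomeIndex,
    assign_gene,
    map_read,
    trim_bwa,
)
from .spatial_quant import AnnotatedRead, SpotGeneCounts, dedup_umis, match_barcode
from .synthetic import SyntheticTranscriptome

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "layout_from_config"]


@dataclass
class PipelineResult:
    """Everything one processing run produces."""

    counts: SpotGeneCounts
    annotated_reads: list[AnnotatedRead]
    status_counts: dict[str, int]
    n_input: int
    n_barcode_matched: int
    n_barcode_discarded: int
    assignments: pd.DataFrame = field(default_factory=pd.DataFrame)

    def check_accounting(self) -> None:
        """Assert the partition invariants; raises AssertionError on breach."""
        assert sum(self.status_counts.values()) == self.n_input, (
            f"status counters {self.status_counts} do not partition "
            f"{self.n_input} input reads"
        )
        assert (
            self.n_barcode_matched + self.n_barcode_discarded
            == self.status_counts["assigned"]
        ), "barcode filter does not partition the assigned reads"
        assert len(self.annotated_reads) == self.n_barcode_matched
        assert self.counts.total_molecules <= self.n_barcode_matched, (
            "deduplicated total exceeds annotated total"
        )


def layout_from_config(config: PipelineConfig) -> ReadLayout:
    return ReadLayout(
        forward_length=config.forward_length,
        reverse_length=config.reverse_length,
        barcode_span=config.barcode_span,
        umi_span=config.umi_span,
    )


def run_pipeline(
    fwd_fastq: str | Path,
    rev_fastq: str | Path,
    design: ArrayDesign,
    transcriptome: SyntheticTranscriptome,
    config: PipelineConfig | None = None,
    keep_assignments: bool = False,
) -> PipelineResult:
    """Process a synchronized paired FASTQ run into unique-molecule counts.

    The reverse read drives the status decision (too_short, ribosomal,
    unmapped, ambiguous, not_polyA or assigned); a forward read too short for
    the barcode + UMI spans also discards the pair as too_short.  Assigned
    reads are then filtered by exact (or bounded-mismatch) barcode membership
    in the array design and deduplicated per (spot, gene, UMI).
    """
    config = config or PipelineConfig()
    layout = layout_from_config(config)
    tx_index = TranscriptomeIndex(transcriptome.sequences(), k=config.map_k)
    rrna_index = RrnaIndex(transcriptome.rrna, k=config.rrna_k)
    annotation = transcriptome.annotation()

    status_counts = {s: 0 for s in STATUSES}
    annotated: list[AnnotatedRead] = []
    rows = [] if keep_assignments else None
    n_input = 0
    n_matched = 0
    n_bc_discarded = 0

    fwd_iter = FastqGeneralIterator(str(fwd_fastq))
    rev_iter = FastqGeneralIterator(str(rev_fastq))
    for fwd_rec, rev_rec in zip_longest(fwd_iter, rev_iter):
        if fwd_rec is None or rev_rec is None:
            raise ValueError(
                "forward and reverse FASTQ files have different record counts"
            )
        (ftitle, fseq, _fq), (_rtitle, rseq, rqual) = fwd_rec, rev_rec
        n_input += 1
        read_id = ftitle.split()[0].split("/")[0]
        status = None
        gene_id = None
        parsed = parse_forward(fseq, layout)

        quals = np.frombuffer(rqual.encode(), dtype=np.uint8).astype(np.int64) - 33
        trimmed = trim_bwa(
            rseq, quals, q_threshold=config.q_threshold, min_length=config.min_length
        )
        if parsed is None or not trimmed.kept:
            status = "too_short"
        elif rrna_index.is_ribosomal(trimmed.seq, min_shared=config.rrna_min_shared):
            status = "ribosomal"
        else:
            candidates = map_read(
                trimmed.seq,
                tx_index,
                min_seeds=config.map_min_seeds,
                stride=config.map_seed_stride,
            )
            assignment = assign_gene(candidates, annotation, read_id=read_id)
            status = assignment.status
            gene_id = assignment.gene_id

        spot = None
        if status == "assigned":
            bc, umi = parsed
            spot = match_barcode(bc, design, max_mismatch=config.max_barcode_mismatch)
            if spot is None:
                n_bc_discarded += 1
            else:
                n_matched += 1
                annotated.append(AnnotatedRead(read_id, spot, gene_id, umi))
        status_counts[status] += 1
        if rows is not None:
            rows.append(
                (
                    read_id,
                    status,
                    gene_id,
                    parsed[0] if parsed else None,
                    parsed[1] if parsed else None,
                    f"{spot[0]}_{spot[1]}" if spot else None,
                )
            )

    polya_genes = transcriptome.polya_gene_ids
    counts = dedup_umis(annotated, design, polya_genes)
    counts.provenance.update(
        reads_in=n_input,
        **{f"status_{k}": v for k, v in status_counts.items()},
        barcode_matched=n_matched,
        barcode_discarded=n_bc_discarded,
    )
    assignments = (
        pd.DataFrame(
            rows, columns=["read_id", "status", "gene_id", "barcode", "umi", "spot"]
        )
        if rows is not None
        else pd.DataFrame()
    )
    result = PipelineResult(
        counts=counts,
        annotated_reads=annotated,
        status_counts=status_counts,
        n_input=n_input,
        n_barcode_matched=n_matched,
        n_barcode_discarded=n_bc_discarded,
        assignments=assignments,
    )
    result.check_accounting()
    logger.info(
        "processed %d read pairs: %s; %d barcode-matched, %d unique molecules",
        n_input,
        status_counts,
        n_matched,
        counts.total_molecules,
    )
    return result
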