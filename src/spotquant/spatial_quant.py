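"""Spot demultiplexing and UMI deduplication into the spot x gene matrix.

Gene-assigned reverse reads are joined to the (barcode, UMI) parsed from
their forward mates, filtered against the array design, and collapsed so
that each distinct (spot, gene, UMI) triple counts as one unique molecule.
"""

from __future__ import annotations

import weakref
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .array_design import ArrayDesign

__all__ = [
    "AnnotatedRead",
    "SpotGeneCounts",
    "match_barcode",
    "dedup_umis",
    "write_counts",
    "read_counts",
]


@dataclass(frozen=True)
class AnnotatedRead:
    """A read resolved to a gene and joined to its spot barcode and UMI."""

    read_id: str
    spot: tuple[int, int]
    gene_id: str
    umi: str

    @property
    def molecule_key(self) -> tuple[tuple[int, int], str, str]:
        return (self.spot, self.gene_id, self.umi)


@dataclass
class SpotGeneCounts:
    """Spots x genes matrix of deduplicated unique-molecule counts.

    ``matrix`` rows are ``"x_y"`` spot labels in design order, columns the
    annotated (polyadenylated) gene universe; ``provenance`` carries the
    run's per-stage counters.
    """

    matrix: pd.DataFrame
    design: Optional[ArrayDesign] = None
    provenance: dict = field(default_factory=dict)

    @property
    def total_molecules(self) -> int:
        return int(self.matrix.to_numpy().sum())

    @property
    def n_genes_detected(self) -> int:
        return int((self.matrix.sum(axis=0) > 0).sum())


_encoded_designs: "weakref.WeakKeyDictionary[ArrayDesign, np.ndarray]" = (
    weakref.WeakKeyDictionary()
)


def _design_matrix(design: ArrayDesign) -> np.ndarray:
    """(n_spots, barcode_length) uint8 view of the design barcodes, cached."""
    enc = _encoded_designs.get(design)
    if enc is None:
        enc = np.frombuffer(
            "".join(design.barcodes).encode(), dtype=np.uint8
        ).reshape(design.n_spots, design.barcode_length)
        _encoded_designs[design] = enc
    return enc


def match_barcode(
    bc: str, design: ArrayDesign, max_mismatch: int = 0
) -> Optional[tuple[int, int]]:
    """Resolve an observed barcode to a design spot, or None.

    An exact hit wins outright.  Otherwise the unique design barcode within
    Hamming distance ``max_mismatch`` is used; two or more candidates tied at
    the minimum distance mean the read cannot be placed and None is returned.
    Length-mismatched barcodes are unplaceable by construction.
    """
    if len(bc) != design.barcode_length:
        return None
    spot = design.spot_of(bc)
    if spot is not None or max_mismatch == 0:
        return spot
    enc = _design_matrix(design)
    query = np.frombuffer(bc.encode(), dtype=np.uint8)
    dists = (enc != query).sum(axis=1)
    best_d = int(dists.min())
    if best_d > max_mismatch or int((dists == best_d).sum()) != 1:
        return None
    _, x, y = design.spots[int(dists.argmin())]
    return (x, y)


def dedup_umis(
    reads: Iterable[AnnotatedRead],
    design: ArrayDesign,
    gene_ids: Sequence[str],
) -> SpotGeneCounts:
    """Collapse PCR duplicates: count distinct (spot, gene, UMI) triples.

    UMI collapse is exact string identity.  The returned matrix covers every
    design spot and every gene in ``gene_ids`` (zeros included) so replicate
    matrices share one universe.  Read order never changes the result.
    """
    triples = {r.molecule_key for r in reads}
    labels = design.spot_labels()
    mat = pd.DataFrame(0, index=labels, columns=list(gene_ids), dtype=np.int64)
    row = {lab: i for i, lab in enumerate(labels)}
    col = {g: j for j, g in enumerate(gene_ids)}
    arr = mat.to_numpy()
    for (x, y), gid, _umi in triples:
        arr[row[f"{x}_{y}"], col[gid]] += 1
    return SpotGeneCounts(mat, design=design, provenance={"unique_molecules": len(triples)})


def write_counts(counts: SpotGeneCounts, path: str | Path, format: str = "tsv") -> Path:
    """Serialize the count matrix as TSV or MatrixMarket (+ label sidecars)."""
    path = Path(path)
    try:
        if format == "tsv":
            counts.matrix.to_csv(path, sep="\t", index_label="spot")
        elif format == "mtx":
            sparse = scipy.sparse.csr_matrix(counts.matrix.to_numpy())
            scipy.io.mmwrite(str(path), sparse)
            path.with_suffix(".rows.txt").write_text(
                "\n".join(counts.matrix.index) + "\n", encoding="utf-8"
            )
            path.with_suffix(".cols.txt").write_text(
                "\n".join(counts.matrix.columns) + "\n", encoding="utf-8"
            )
        else:
            raise ValueError(f"unknown format {format!r}")
    except OSError as exc:
        raise OSError(f"failed writing counts to {path}: {exc}") from exc
    return path


def read_counts(path: str | Path, format: str = "tsv") -> SpotGeneCounts:
    """Inverse of :func:`write_counts` (design reference is not recoverable)."""
    path = Path(path)
    try:
        if format == "tsv":
            mat = pd.read_csv(path, sep="\t", index_col="spot")
            mat.columns.name = None
            return SpotGeneCounts(mat.astype(np.int64))
        if format == "mtx":
            sparse = scipy.io.mmread(str(path)).tocsr()
            rows = path.with_suffix(".rows.txt").read_text(encoding="utf-8").splitlines()
            cols = path.with_suffix(".cols.txt").read_text(encoding="utf-8").splitlines()
            mat = pd.DataFrame(
                sparse.toarray().astype(np.int64), index=rows, columns=cols
            )
            return SpotGeneCounts(mat)
        raise ValueError(f"unknown format {format!r}")
    except OSError as exc:
        raise OSError(f"failed reading counts from {path}: {exc}") from exc
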