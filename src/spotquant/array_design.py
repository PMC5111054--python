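"""Barcoded array layout and forward-read structure.

A spatially barcoded array prints capture probes in a grid of spots; every
probe within a spot carries the same spot-specific DNA barcode, followed by a
semi-randomized unique molecular identifier (UMI).  The forward read of each
pair sequences barcode + UMI, so each captured transcript can be mapped back
to an (x, y) position on the array and PCR copies of one molecule can be
collapsed.

This module defines the array design (barcode -> coordinate map) and the
read layout (where barcode and UMI sit on the forward read), together with
TSV round-trip I/O and forward-read parsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "ArrayDesign",
    "ReadLayout",
    "load_array_design",
    "write_array_design",
    "parse_forward",
    "iupac_matches",
]

_DNA = frozenset("ACGT")

#: Allowed IUPAC ambiguity codes and the concrete bases each stands for.
IUPAC_CODES: dict[str, str] = {
    code: bases for code, bases in ambiguous_dna_values.items() if code != "X"
}


def iupac_matches(base: str, code: str) -> bool:
    """True if ``base`` is one of the concrete bases the IUPAC ``code`` allows."""
    return base in IUPAC_CODES.get(code, "")


@dataclass(frozen=True)
class ArrayDesign:
    """Map from spot barcode sequence to array spot coordinates.

    Parameters
    ----------
    spots
        Sequence of ``(barcode, x, y)`` with 0-based integer grid indices.
    umi_length
        Length of the UMI on the forward read, in bases.
    umi_pattern
        IUPAC string of length ``umi_length`` describing the semi-randomized
        UMI (e.g. ``"WSNNWSNNV"``).
    """

    spots: tuple[tuple[str, int, int], ...]
    umi_length: int = 9
    umi_pattern: str = "WSNNWSNNV"
    _barcode_to_spot: dict[str, tuple[int, int]] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        spots = tuple((str(bc), int(x), int(y)) for bc, x, y in self.spots)
        object.__setattr__(self, "spots", spots)
        if not spots:
            raise ValueError("array design has no spots")
        lengths = {len(bc) for bc, _, _ in spots}
        if len(lengths) != 1:
            raise ValueError(f"ragged barcode lengths: {sorted(lengths)}")
        seen_bc: dict[str, tuple[int, int]] = {}
        seen_xy: set[tuple[int, int]] = set()
        for bc, x, y in spots:
            if set(bc) - _DNA:
                raise ValueError(f"barcode {bc!r} contains non-ACGT characters")
            if bc in seen_bc:
                raise ValueError(f"duplicate barcode {bc!r}")
            if (x, y) in seen_xy:
                raise ValueError(f"duplicate spot coordinate {(x, y)}")
            seen_bc[bc] = (x, y)
            seen_xy.add((x, y))
        if len(self.umi_pattern) != self.umi_length:
            raise ValueError(
                f"umi_pattern length {len(self.umi_pattern)} != umi_length {self.umi_length}"
            )
        bad = [c for c in self.umi_pattern if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"umi_pattern has non-IUPAC codes: {bad}")
        object.__setattr__(self, "_barcode_to_spot", seen_bc)

    @property
    def barcode_length(self) -> int:
        return len(self.spots[0][0])

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def barcodes(self) -> list[str]:
        return [bc for bc, _, _ in self.spots]

    @property
    def coordinates(self) -> list[tuple[int, int]]:
        return [(x, y) for _, x, y in self.spots]

    def spot_of(self, barcode: str) -> Optional[tuple[int, int]]:
        """Exact-match lookup of a barcode's spot, or None."""
        return self._barcode_to_spot.get(barcode)

    def spot_labels(self) -> list[str]:
        """Stable ``"x_y"`` labels, one per spot, in design order."""
        return [f"{x}_{y}" for _, x, y in self.spots]


@dataclass(frozen=True)
class ReadLayout:
    """Positions of barcode and UMI on the forward read.

    Spans are 0-based half-open intervals on the forward read.  Defaults model
    a 36 bp forward / 121 bp reverse pair with an 18 bp barcode immediately
    followed by a 9 bp UMI; forward bases after the UMI are ignored.
    """

    forward_length: int = 36
    reverse_length: int = 121
    barcode_span: tuple[int, int] = (0, 18)
    umi_span: tuple[int, int] = (18, 27)

    def __post_init__(self) -> None:
        for name, (a, b) in (("barcode_span", self.barcode_span), ("umi_span", self.umi_span)):
            if not (0 <= a < b <= self.forward_length):
                raise ValueError(f"{name} {a, b} outside forward read of {self.forward_length} bp")
        b0, b1 = self.barcode_span
        u0, u1 = self.umi_span
        if max(b0, u0) < min(b1, u1):
            raise ValueError("barcode_span and umi_span overlap")

    @property
    def barcode_length(self) -> int:
        return self.barcode_span[1] - self.barcode_span[0]

    @property
    def umi_length(self) -> int:
        return self.umi_span[1] - self.umi_span[0]

    @property
    def min_forward_length(self) -> int:
        return max(self.barcode_span[1], self.umi_span[1])


def parse_forward(seq: str, layout: ReadLayout) -> Optional[tuple[str, str]]:
    """Extract (barcode, umi) from a forward read.

    Returns None when the read is shorter than the spans require; such reads
    are discarded by the caller rather than raising.
    """
    if len(seq) < layout.min_forward_length:
        return None
    b0, b1 = layout.barcode_span
    u0, u1 = layout.umi_span
    return seq[b0:b1], seq[u0:u1]


def load_array_design(
    path: str | Path, umi_length: int = 9, umi_pattern: str = "WSNNWSNNV"
) -> ArrayDesign:
    """Load an array design from a TSV with header ``barcode\\tx\\ty``.

    Barcode length is inferred from the data; duplicate or malformed
    barcodes raise ValueError naming the offender.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["barcode", "x", "y"]:
            raise ValueError(f"{path}: expected header 'barcode\\tx\\ty', got {header!r}")
        spots = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            bc, x, y = parts[0], int(parts[1]), int(parts[2])
            spots.append((bc, x, y))
    return ArrayDesign(tuple(spots), umi_length=umi_length, umi_pattern=umi_pattern)


def write_array_design(design: ArrayDesign, path: str | Path) -> Path:
    """Write the design as the TSV that :func:`load_array_design` reads."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("barcode\tx\ty\n")
        for bc, x, y in design.spots:
            fh.write(f"{bc}\t{x}\t{y}\n")
    return path
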