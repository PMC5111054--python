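"""Run configuration: one flat record of every tunable knob, YAML-serializable."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Tunables for read structure, trimming, filtering, mapping and counting.

    Defaults model the 36 bp forward / 121 bp reverse paired layout with an
    18 bp spot barcode and a 9 bp semi-randomized UMI; all values are
    overridable from a YAML file.
    """

    # forward/reverse read structure
    forward_length: int = 36
    reverse_length: int = 121
    barcode_length: int = 18
    umi_length: int = 9
    umi_pattern: str = "WSNNWSNNV"

    # BWA-style 3' quality trimming
    q_threshold: int = 20
    min_length: int = 25

    # ribosomal k-mer screen
    rrna_k: int = 15
    rrna_min_shared: int = 2

    # transcriptome k-mer mapper
    map_k: int = 15
    map_min_seeds: int = 2
    map_seed_stride: int = 5

    # spot barcode matching
    max_barcode_mismatch: int = 0

    def __post_init__(self) -> None:
        if len(self.umi_pattern) != self.umi_length:
            raise ValueError("umi_pattern length must equal umi_length")
        if self.barcode_length + self.umi_length > self.forward_length:
            raise ValueError("barcode + UMI exceed forward read length")

    @property
    def barcode_span(self) -> tuple[int, int]:
        return (0, self.barcode_length)

    @property
    def umi_span(self) -> tuple[int, int]:
        return (self.barcode_length, self.barcode_length + self.umi_length)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
        return path
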