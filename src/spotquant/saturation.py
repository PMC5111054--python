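"""Library-complexity saturation by down-sampling annotated reads.

Down-sampling the annotated reads to predefined depths and counting the
unique (spot, gene, UMI) triples recovered at each depth estimates library
diversity and shows whether sequencing approached saturation: the curve
plateaus once nearly every captured molecule has been seen at least once.
A matched raw-FASTQ down-sampler mirrors depth-equalization across
libraries before processing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SaturationCurve",
    "saturation_curve",
    "expected_unique",
    "downsample_fastq",
]


@dataclass(frozen=True)
class SaturationCurve:
    """Unique molecules recovered as a function of sampled read depth."""

    depths: tuple[int, ...]
    unique_transcripts: tuple[float, ...]  # mean over replicates
    sd: tuple[float, ...]
    n_replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": self.depths,
                "mean_unique": self.unique_transcripts,
                "sd_unique": self.sd,
            }
        )

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


def default_depths(total_reads: int, n_points: int = 10) -> list[int]:
    """Evenly spaced depths from total/n_points up to the full read count."""
    return [int(round(total_reads * (i + 1) / n_points)) for i in range(n_points)]


def saturation_curve(
    reads: Sequence[Hashable],
    depths: Optional[Sequence[int]] = None,
    n_replicates: int = 1,
    seed: int = 0,
) -> SaturationCurve:
    """Down-sample the annotated-read multiset and count unique molecules.

    ``reads`` is one molecule key per annotated read (duplicates repeated).
    For each replicate a fresh permutation is drawn, and the unique count at
    depth d is the number of distinct keys among its first d reads — a
    uniform without-replacement sample that is nested across depths, so each
    replicate's curve is monotone non-decreasing by construction.  Per-depth
    means and standard deviations over replicates are reported.
    """
    keys = np.empty(len(reads), dtype=object)  # 1-D even when keys are tuples
    keys[:] = list(reads)
    codes, _uniques = pd.factorize(keys)
    n = len(codes)
    n_mol = codes.max() + 1 if n else 0
    if depths is None:
        depths = default_depths(n)
    depths = [int(d) for d in depths]
    for d in depths:
        if d > n:
            raise ValueError(f"depth {d} exceeds total annotated reads ({n})")
        if d < 0:
            raise ValueError(f"negative depth {d}")
    rng = np.random.default_rng(seed)
    per_rep = np.empty((n_replicates, len(depths)), dtype=np.int64)
    for rep in range(n_replicates):
        perm = rng.permutation(n)
        # first position at which each molecule appears in this permutation
        first_pos = np.full(n_mol, n, dtype=np.int64)
        np.minimum.at(first_pos, codes[perm], np.arange(n))
        first_pos.sort()
        per_rep[rep] = np.searchsorted(first_pos, depths, side="left")
    means = per_rep.mean(axis=0)
    sds = per_rep.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros(len(depths))
    return SaturationCurve(
        tuple(depths),
        tuple(float(m) for m in means),
        tuple(float(s) for s in sds),
        n_replicates,
        seed,
    )


def expected_unique(copy_counts: Sequence[int], depth: int) -> float:
    """Closed-form expected unique molecules in a without-replacement sample.

    With N total reads and molecule m represented by c_m duplicate reads, the
    chance that m is missed entirely by a uniform sample of d reads is
    hypergeometric: C(N - c_m, d) / C(N, d).  The expectation is
    sum_m [1 - C(N - c_m, d) / C(N, d)], evaluated in log space.
    """
    c = np.asarray(copy_counts, dtype=np.int64)
    n = int(c.sum())
    if depth > n:
        raise ValueError(f"depth {depth} exceeds total reads ({n})")
    # log C(N - c, d) - log C(N, d) = log[(N-c)! d! (N-d)!] - log[(N-c-d)! d! N!]
    with np.errstate(invalid="ignore"):
        log_miss = (
            gammaln(n - c + 1)
            + gammaln(n - depth + 1)
            - gammaln(n - c - depth + 1)
            - gammaln(n + 1)
        )
    miss = np.where(n - c - depth < 0, 0.0, np.exp(log_miss))
    return float(np.sum(1.0 - miss))


def downsample_fastq(
    fwd_in: str | Path,
    rev_in: str | Path,
    n: int,
    seed: int,
    fwd_out: str | Path,
    rev_out: str | Path,
) -> tuple[Path, Path]:
    """Keep the same n uniformly chosen records from a synchronized FASTQ pair.

    The forward and reverse files must hold the same records in the same
    order; the selected indices are applied to both so pairing and relative
    order are preserved.
    """
    fwd = list(FastqGeneralIterator(str(fwd_in)))
    rev = list(FastqGeneralIterator(str(rev_in)))
    if len(fwd) != len(rev):
        raise ValueError(
            f"desynchronized pair: {len(fwd)} forward vs {len(rev)} reverse records"
        )
    if n > len(fwd):
        raise ValueError(f"cannot sample {n} from {len(fwd)} record pairs")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(fwd), size=n, replace=False))
    fwd_out, rev_out = Path(fwd_out), Path(rev_out)
    with open(fwd_out, "w") as ffh, open(rev_out, "w") as rfh:
        for i in keep:
            t, s, q = fwd[i]
            ffh.write(f"@{t}\n{s}\n+\n{q}\n")
            t, s, q = rev[i]
            rfh.write(f"@{t}\n{s}\n+\n{q}\n")
    return fwd_out, rev_out
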