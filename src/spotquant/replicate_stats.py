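"""Between-replicate concordance: normalization, correlation, dispersion.

Replicate tissue sections are compared either in bulk (per-gene counts summed
over all spots) or within a selected region (per-gene counts averaged over
its spots).  Sample vectors are depth-normalized with the median-of-ratios
size-factor estimator, transformed as log2(x + 1), and compared by pairwise
Pearson correlation; the coefficient of variation summarizes replicate
dispersion for scalar quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .spatial_quant import SpotGeneCounts

__all__ = [
    "CorrelationReport",
    "bulk_sum",
    "region_average",
    "size_factors",
    "normalize_counts",
    "log2_pseudo",
    "pearson_matrix",
    "coefficient_of_variation",
]


def bulk_sum(counts: SpotGeneCounts, sample_id: str = "sample") -> pd.Series:
    """Per-gene counts summed over all spatial barcodes in the sample."""
    s = counts.matrix.sum(axis=0)
    s.name = sample_id
    return s


def region_average(
    counts: SpotGeneCounts,
    region: Sequence[tuple[int, int]],
    sample_id: str = "sample",
) -> pd.Series:
    """Per-gene arithmetic mean over the region's spots.

    Spots with zero counts contribute zeros to the mean (the denominator is
    always ``len(region)``); this is the averaged pseudo-spot used to compare
    a selected region — e.g. ten spots under an inflamed area — across
    replicate sections.
    """
    if not len(region):
        raise ValueError("region is empty")
    labels = [f"{x}_{y}" for x, y in region]
    missing = [lab for lab in labels if lab not in counts.matrix.index]
    if missing:
        raise ValueError(f"region spots not in matrix: {missing}")
    s = counts.matrix.loc[labels].mean(axis=0)
    s.name = sample_id
    return s


def _as_frame(samples: Sequence[pd.Series] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        return samples
    df = pd.concat(list(samples), axis=1)
    if df.isna().any().any():
        raise ValueError("samples do not share one gene universe")
    return df


def size_factors(samples: Sequence[pd.Series] | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes x samples input).

    For sample j, s_j is the median over genes g — restricted to genes with a
    nonzero count in every sample — of count_gj divided by the geometric mean
    of gene g's counts across samples.  Dividing each sample by its factor
    removes pure sequencing-depth differences.
    """
    df = _as_frame(samples)
    if df.shape[1] < 2:
        raise ValueError("need at least two samples")
    mat = df.to_numpy(dtype=float)
    everywhere = (mat > 0).all(axis=1)
    if not everywhere.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "consider pseudo-bulking or filtering genes first"
        )
    sub = mat[everywhere]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_geomean)
    return pd.Series(np.median(ratios, axis=0), index=df.columns, name="size_factor")


def normalize_counts(samples: Sequence[pd.Series] | pd.DataFrame) -> pd.DataFrame:
    """Counts divided by their median-of-ratios size factors."""
    df = _as_frame(samples)
    return df / size_factors(df)


def log2_pseudo(values):
    """log2(v + 1) elementwise; the standard pseudo-count transform."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("log2_pseudo requires non-negative input")
    out = np.log2(arr + 1.0)
    if isinstance(values, (pd.Series, pd.DataFrame)):
        return values.__class__(out, index=values.index, **(
            {"columns": values.columns} if isinstance(values, pd.DataFrame) else {"name": values.name}
        ))
    return out


@dataclass(frozen=True)
class CorrelationReport:
    """Pairwise Pearson correlations on transformed sample vectors."""

    sample_ids: tuple[str, ...]
    matrix: pd.DataFrame

    @property
    def mean_r(self) -> float:
        """Arithmetic mean of the off-diagonal pairwise correlations."""
        m = self.matrix.to_numpy()
        n = m.shape[0]
        off = m[~np.eye(n, dtype=bool)]
        return float(off.mean())

    def pair(self, a: str, b: str) -> float:
        return float(self.matrix.loc[a, b])


def pearson_matrix(samples: Sequence[pd.Series] | pd.DataFrame) -> CorrelationReport:
    """Pairwise Pearson r over the shared gene vectors.

    Computed on the full common gene universe, zeros included; intended to be
    applied after normalization and log2(x + 1).  A zero-variance sample
    vector makes r undefined and raises, naming the sample.
    """
    df = _as_frame(samples)
    if df.shape[1] < 2:
        raise ValueError("need at least two samples")
    sds = df.std(axis=0, ddof=0)
    flat = sds[sds == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance sample vector(s): {flat}")
    corr = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    mat = pd.DataFrame(corr, index=df.columns, columns=df.columns)
    return CorrelationReport(tuple(df.columns), mat)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample CV in percent: 100 * sd (n-1 denominator) / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)
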