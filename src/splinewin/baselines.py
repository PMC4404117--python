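"""Fixed-size sliding and distinct window baselines.

Both methods segment a chromosome into windows containing a fixed number of
SNPs.  Distinct windows are consecutive non-overlapping blocks; sliding
windows advance by ``step_snps`` (default 1, so every possible window is
scored).  The per-window statistic is the arithmetic mean of the member
SNPs' values; window genomic spans are reported as
[first SNP position, last SNP position + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import MarkerSeries

__all__ = ["FixedWindowResult", "distinct_windows", "sliding_windows"]


@dataclass(frozen=True)
class FixedWindowResult:
    """Fixed-size window means for one chromosome."""

    method: str            # "sliding" or "distinct"
    size_snps: int
    step_snps: int
    chrom: str
    start: np.ndarray      # bp, half-open spans
    stop: np.ndarray
    first_idx: np.ndarray  # SNP index bounds, inclusive
    last_idx: np.ndarray
    mean: np.ndarray
    n_dropped: int = 0     # trailing SNPs not covered (distinct only)

    def __len__(self) -> int:
        return int(self.mean.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "CHROM": self.chrom,
                "WindowStart": self.start,
                "WindowStop": self.stop,
                "SNPcount": self.size_snps,
                "MeanY": self.mean,
                "METHOD": self.method,
                "SIZE": self.size_snps,
            }
        )


def _window_means(values: np.ndarray, size: int, step: int) -> np.ndarray:
    """Rolling mean at the given step via cumulative sums (O(n))."""
    c = np.concatenate(([0.0], np.cumsum(values)))
    starts = np.arange(0, values.size - size + 1, step)
    return (c[starts + size] - c[starts]) / size


def sliding_windows(series: MarkerSeries, size_snps: int, step_snps: int = 1) -> FixedWindowResult:
    """Overlapping windows of ``size_snps`` SNPs advanced by ``step_snps``."""
    n = len(series)
    if size_snps < 1 or step_snps < 1:
        raise ValueError("size_snps and step_snps must be >= 1")
    if size_snps > n:
        raise ValueError(f"window larger than chromosome: {size_snps} > {n} SNPs")
    starts = np.arange(0, n - size_snps + 1, step_snps)
    means = _window_means(series.values, size_snps, step_snps)
    first = starts
    last = starts + size_snps - 1
    return FixedWindowResult(
        method="sliding",
        size_snps=size_snps,
        step_snps=step_snps,
        chrom=series.chrom,
        start=series.positions[first].copy(),
        stop=series.positions[last] + 1,
        first_idx=first,
        last_idx=last,
        mean=means,
    )


def distinct_windows(series: MarkerSeries, size_snps: int) -> FixedWindowResult:
    """Non-overlapping blocks of exactly ``size_snps`` SNPs.

    A trailing block with fewer than ``size_snps`` SNPs is dropped so all
    windows are of equal length; the drop count is reported.
    """
    n = len(series)
    if size_snps < 1:
        raise ValueError("size_snps must be >= 1")
    if size_snps > n:
        raise ValueError(f"window larger than chromosome: {size_snps} > {n} SNPs")
    res = sliding_windows(series, size_snps, step_snps=size_snps)
    n_dropped = n - (n // size_snps) * size_snps
    return FixedWindowResult(
        method="distinct",
        size_snps=size_snps,
        step_snps=size_snps,
        chrom=res.chrom,
        start=res.start,
        stop=res.stop,
        first_idx=res.first_idx,
        last_idx=res.last_idx,
        mean=res.mean,
        n_dropped=n_dropped,
    )
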