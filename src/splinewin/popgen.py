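"""Per-marker FST and the two-stage binomial Pool-seq sampling model.

FST between two populations at one biallelic marker uses the two-population
variance estimator

    FST = s^2 / (p_bar (1 - p_bar) + s^2 / r),    r = 2,

where ``s^2`` is the sample variance of the allele frequency between the two
populations (r - 1 = 1 denominator, so s^2 = (p1 - p2)^2 / 2) and ``p_bar``
their mean.  The estimator is bounded in [0, 1], symmetric in the two
populations, and invariant to relabeling the reference allele.

Pooled sequencing of n diploid individuals at coverage c is modeled as two
nested binomial draws: first 2n gametes from the population frequency, then
c reads from the sampled individuals.  The resulting frequency estimate is
unbiased with variance  p(1-p) * (1/(2n) + (1 - 1/(2n))/c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FreqPair",
    "PoolSpec",
    "fst_per_marker",
    "fst_array",
    "pooled_seq_sample",
    "pooled_seq_sample_array",
    "fst_table",
]


@dataclass(frozen=True)
class FreqPair:
    """Reference-allele frequencies of one marker in two populations."""

    p_pre: float
    p_post: float

    def __post_init__(self) -> None:
        for p in (self.p_pre, self.p_post):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"frequency {p} outside [0, 1]")


@dataclass(frozen=True)
class PoolSpec:
    """Pool-seq sampling design: diploid pool size and read coverage."""

    n_individuals: int = 100
    coverage: int = 50

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.coverage < 1:
            raise ValueError("n_individuals and coverage must be >= 1")


def fst_per_marker(pair: FreqPair) -> float:
    """Two-population FST for one marker; raises on monomorphic input."""
    p1, p2 = pair.p_pre, pair.p_post
    pbar = 0.5 * (p1 + p2)
    if pbar <= 0.0 or pbar >= 1.0:
        raise ValueError("monomorphic marker: mean frequency is 0 or 1")
    s2 = 0.5 * (p1 - p2) ** 2
    return float(s2 / (pbar * (1.0 - pbar) + 0.5 * s2))


def fst_array(p_pre: np.ndarray, p_post: np.ndarray) -> np.ndarray:
    """Vectorized FST; monomorphic markers (p_bar in {0,1}) yield NaN.

    Callers are expected to drop the NaN rows (see :func:`fst_table`); the
    spline input itself must be NaN-free.
    """
    p1 = np.asarray(p_pre, dtype=np.float64)
    p2 = np.asarray(p_post, dtype=np.float64)
    pbar = 0.5 * (p1 + p2)
    s2 = 0.5 * (p1 - p2) ** 2
    denom = pbar * (1.0 - pbar) + 0.5 * s2
    out = np.full(p1.shape, np.nan)
    ok = (pbar > 0.0) & (pbar < 1.0)
    out[ok] = s2[ok] / denom[ok]
    return out


def pooled_seq_sample(true_freq: float, spec: PoolSpec, rng=None) -> float:
    """One pooled-sequencing frequency estimate for one marker.

    Stage 1: k ~ Binomial(2 * n_individuals, true_freq), p' = k / 2n.
    Stage 2: m ~ Binomial(coverage, p'); returns m / coverage.
    """
    rng = np.random.default_rng(rng)
    two_n = 2 * spec.n_individuals
    k = rng.binomial(two_n, true_freq)
    m = rng.binomial(spec.coverage, k / two_n)
    return float(m / spec.coverage)


def pooled_seq_sample_array(true_freqs: np.ndarray, spec: PoolSpec, rng=None) -> np.ndarray:
    """Vectorized two-stage pooled sampling over an array of frequencies."""
    rng = np.random.default_rng(rng)
    p = np.asarray(true_freqs, dtype=np.float64)
    two_n = 2 * spec.n_individuals
    k = rng.binomial(two_n, p)
    m = rng.binomial(spec.coverage, k / two_n)
    return m / spec.coverage


def fst_table(freqs: pd.DataFrame) -> pd.DataFrame:
    """CHROM/POS/FREQ_PRE/FREQ_POST (or pooled counts) -> CHROM/POS/FST.

    Accepts either FREQ_PRE + FREQ_POST columns or raw pooled read counts
    (REF_COUNT_PRE, DEPTH_PRE, REF_COUNT_POST, DEPTH_POST), from which
    frequencies are count/depth.  Monomorphic markers are dropped; the drop
    count is recorded in ``df.attrs['n_monomorphic_dropped']``.
    """
    cols = set(freqs.columns)
    if {"FREQ_PRE", "FREQ_POST"} <= cols:
        p1 = freqs["FREQ_PRE"].to_numpy(float)
        p2 = freqs["FREQ_POST"].to_numpy(float)
    elif {"REF_COUNT_PRE", "DEPTH_PRE", "REF_COUNT_POST", "DEPTH_POST"} <= cols:
        p1 = freqs["REF_COUNT_PRE"].to_numpy(float) / freqs["DEPTH_PRE"].to_numpy(float)
        p2 = freqs["REF_COUNT_POST"].to_numpy(float) / freqs["DEPTH_POST"].to_numpy(float)
    else:
        raise ValueError(
            "need FREQ_PRE/FREQ_POST or REF_COUNT_*/DEPTH_* columns, got "
            + ", ".join(sorted(cols))
        )
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("frequencies outside [0, 1]")
    fst = fst_array(p1, p2)
    keep = np.isfinite(fst)
    out = pd.DataFrame(
        {
            "CHROM": freqs["CHROM"].to_numpy()[keep],
            "POS": freqs["POS"].to_numpy()[keep],
            "FST": fst[keep],
        }
    )
    out.attrs["n_monomorphic_dropped"] = int((~keep).sum())
    return out
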