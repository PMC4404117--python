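"""Readers, writers, and synthetic fixtures.

Marker tables are whitespace- or tab-delimited text with a header carrying
CHROM, POS, VALUE.  Window tables mirror the classic spline-window output
roster: CHROM, WindowStart, WindowStop, SNPcount, MeanY, Wstat.  Inputs are
1-based bp; the optional BED6 export shifts to 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .windows import MarkerSeries, WindowSet

__all__ = [
    "read_marker_table",
    "write_window_table",
    "window_table",
    "make_fixture",
]


def read_marker_table(path, value_col: str = "VALUE") -> list[MarkerSeries]:
    """Read a delimited marker table into per-chromosome series.

    Rows are grouped by chromosome and sorted by position.  Duplicate
    (CHROM, POS) rows and non-finite values are rejected with the offending
    line numbers (1-based, counting the header as line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.upper() for c in df.columns]
    required = {"CHROM", "POS", value_col.upper()}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    vcol = value_col.upper()
    vals = pd.to_numeric(df[vcol], errors="coerce")
    bad = ~np.isfinite(vals.to_numpy(float))
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: non-finite {vcol} at line(s) {lines[:10]}")
    dup = df.duplicated(subset=["CHROM", "POS"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise ValueError(f"{path}: duplicate (CHROM, POS) at line(s) {lines[:10]}")
    series = []
    for chrom, g in df.groupby("CHROM", sort=True):
        g = g.sort_values("POS")
        series.append(
            MarkerSeries(str(chrom), g["POS"].to_numpy(np.int64), g[vcol].to_numpy(float))
        )
    return series


def window_table(window_set: WindowSet) -> pd.DataFrame:
    """WindowSet -> the standard output table."""
    return pd.DataFrame(
        {
            "CHROM": [w.chrom for w in window_set],
            "WindowStart": [w.start for w in window_set],
            "WindowStop": [w.stop for w in window_set],
            "SNPcount": [w.n for w in window_set],
            "MeanY": [w.mean_y for w in window_set],
            "Wstat": [w.w_stat for w in window_set],
        }
    )


def write_window_table(window_set: WindowSet, path, format: str = "tsv") -> None:
    """Write windows as TSV (1-based, half-open) or BED6 (0-based).

    BED score is W clipped to [0, 1000] after scaling by 100; strand is '.'.
    """
    df = window_table(window_set)
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "bed":
        bed = pd.DataFrame(
            {
                "chrom": df["CHROM"],
                "chromStart": df["WindowStart"] - 1,
                "chromEnd": df["WindowStop"] - 1,
                "name": [f"window_{i}" for i in range(len(df))],
                "score": np.clip(df["Wstat"] * 100, 0, 1000).round().astype(int),
                "strand": ".",
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def make_fixture(kind: str, params: dict | None = None, seed: int = 0) -> MarkerSeries:
    """Deterministic synthetic marker series for tests and examples.

    kinds:
      constant    — flat value (default 0.3) at ``n`` uniform positions
      sine        — sin(2 pi t / period) + Normal(0, noise_sd)
      bump        — Gaussian bump of height ``height`` at ``center`` + noise
      figure1     — 200 markers over 1 Mb, one bump + noise (single-peak
                    chromosome region in the style of a method walkthrough)
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    n = int(params.pop("n", 200))
    span = int(params.pop("span", 1_000_000))
    chrom = str(params.pop("chrom", "1"))
    pos = np.sort(rng.choice(np.arange(1, span + 1), size=n, replace=False))

    if kind == "constant":
        value = float(params.pop("value", 0.3))
        y = np.full(n, value)
    elif kind == "sine":
        period = float(params.pop("period", span / 4))
        noise = float(params.pop("noise_sd", 0.05))
        y = np.sin(2 * np.pi * pos / period) + rng.normal(0, noise, n)
    elif kind in ("bump", "figure1"):
        center = float(params.pop("center", span / 2))
        width = float(params.pop("width", span / 20))
        height = float(params.pop("height", 0.5))
        base = float(params.pop("base", 0.1))
        noise = float(params.pop("noise_sd", 0.05))
        y = base + height * np.exp(-0.5 * ((pos - center) / width) ** 2)
        y = y + rng.normal(0, noise, n)
        y = np.clip(y, 0.0, None)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if params:
        raise ValueError(f"unused fixture params: {sorted(params)}")
    return MarkerSeries(chrom, pos, y)
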