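"""Null-calibrated thresholds, TP/FP scoring, method comparison, outlier scan.

Thresholding follows the simulation-based multiple-testing correction: for
each window method, record the maximum window statistic in each unselected
(null) replicate and take the 95% quantile of those maxima as the
genome-wide significance threshold.  Windows exceeding the threshold in a
selection replicate are true positives if any point of their span lies
within 5 cM of a simulated QTL (each QTL counted at most once per
replicate) and false positives otherwise.  Methods are compared by the
ratio of mean detections to mean false positives per replicate.

The empirical-scan protocol (for real datasets) instead flags windows above
the 99.9% empirical quantile of the W statistic and merges flagged windows
within 5 Mb of one another into candidate selected regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import distinct_windows, sliding_windows
from .popgen import PoolSpec, fst_table
from .simulate import SimConfig, SimReplicate, emit_pooled_dataset, simulate_replicate
from .windows import MarkerSeries, WindowSet, spline_analyze

__all__ = [
    "ThresholdSpec",
    "EvalResult",
    "OutlierRegion",
    "null_threshold",
    "classify",
    "compare_methods",
    "run_benchmark",
    "scan",
    "merge_outliers",
    "series_from_fst",
    "method_windows",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-null-replicate maxima and the derived quantile threshold."""

    maxima: np.ndarray
    quantile: float
    threshold: float


@dataclass(frozen=True)
class EvalResult:
    """One method's row of the comparison table."""

    method: str
    mean_detected: float
    mean_false_positives: float
    ratio: float
    threshold: float
    n_qtl_total: int


@dataclass(frozen=True)
class OutlierRegion:
    """A merged run of outlying windows."""

    chrom: str
    start: int
    stop: int
    windows: pd.DataFrame = field(compare=False)
    max_w: float = float("nan")


def null_threshold(maxima, q: float = 0.95) -> ThresholdSpec:
    """Quantile of per-null-replicate maxima, linear interpolation between
    order statistics (so maxima 1..20 at q = 0.95 give 19.05)."""
    arr = np.asarray(maxima, dtype=np.float64)
    if arr.size < 1:
        raise ValueError("no null replicates")
    if arr.size < 2:
        raise ValueError("need >= 2 null maxima to form a threshold")
    thr = float(np.quantile(arr, q, method="linear"))
    return ThresholdSpec(maxima=arr, quantile=q, threshold=thr)


def classify(
    sig_windows: pd.DataFrame,
    qtl: pd.DataFrame,
    radius_cm: float = 5.0,
    cm_per_bp: float | None = None,
) -> tuple[int, int]:
    """Count (detected QTL, false positives) for one replicate.

    ``sig_windows`` needs CHROM/WindowStart/WindowStop; ``qtl`` needs
    CHROM/POS.  A window is attributed to a QTL when the cM distance from
    its nearest edge (or 0 if the QTL lies inside the span) is at most
    ``radius_cm``; each QTL is detected at most once; every significant
    window near no QTL adds one false positive.
    """
    if cm_per_bp is None:
        raise ValueError("a genetic map (cm_per_bp) is required")
    detected: set[tuple[str, int]] = set()
    n_fp = 0
    qtl_by_chrom = {str(c): g["POS"].to_numpy(np.float64) for c, g in qtl.groupby("CHROM")}
    for row in sig_windows.itertuples(index=False):
        chrom = str(row.CHROM)
        qs = qtl_by_chrom.get(chrom)
        if qs is None or qs.size == 0:
            n_fp += 1
            continue
        lo = float(row.WindowStart) * cm_per_bp
        hi = float(row.WindowStop) * cm_per_bp
        qcm = qs * cm_per_bp
        dist = np.maximum(0.0, np.maximum(lo - qcm, qcm - hi))
        near = dist <= radius_cm
        if near.any():
            for q in qs[near]:
                detected.add((chrom, int(q)))
        else:
            n_fp += 1
    return len(detected), n_fp


def series_from_fst(fst: pd.DataFrame) -> list[MarkerSeries]:
    """Split a CHROM/POS/FST table into per-chromosome marker series."""
    out = []
    for c, g in fst.groupby("CHROM", sort=True):
        g = g.sort_values("POS")
        out.append(
            MarkerSeries(str(c), g["POS"].to_numpy(np.int64), g["FST"].to_numpy(float))
        )
    return out


def method_windows(
    method: str,
    fst: pd.DataFrame,
    criterion: str = "gcv",
    resolution_bp: int = 100,
) -> pd.DataFrame:
    """Apply one roster method to a replicate's FST table.

    ``method`` is ``"spline"`` or ``"{sliding|distinct}-<k>"``.  Returns a
    window table with CHROM/WindowStart/WindowStop/SNPcount/STAT, where STAT
    is W for spline windows and the window mean FST for fixed windows.
    """
    frames = []
    for series in series_from_fst(fst):
        if method == "spline":
            ws = spline_analyze(series, criterion=criterion, resolution_bp=resolution_bp)
            frames.append(
                pd.DataFrame(
                    {
                        "CHROM": series.chrom,
                        "WindowStart": [w.start for w in ws],
                        "WindowStop": [w.stop for w in ws],
                        "SNPcount": [w.n for w in ws],
                        "STAT": [w.w_stat for w in ws],
                    }
                )
            )
        else:
            try:
                kind, size_s = method.split("-")
                size = int(size_s)
            except ValueError as exc:
                raise ValueError(f"unknown method {method!r}") from exc
            if kind == "sliding":
                res = sliding_windows(series, size)
            elif kind == "distinct":
                res = distinct_windows(series, size)
            else:
                raise ValueError(f"unknown method {method!r}")
            frames.append(
                pd.DataFrame(
                    {
                        "CHROM": series.chrom,
                        "WindowStart": res.start,
                        "WindowStop": res.stop,
                        "SNPcount": res.size_snps,
                        "STAT": res.mean,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def compare_methods(
    selected: list[tuple[pd.DataFrame, pd.DataFrame]],
    null: list[pd.DataFrame],
    roster: list[str],
    cm_per_bp: float,
    radius_cm: float = 5.0,
    quantile: float = 0.95,
    criterion: str = "gcv",
    resolution_bp: int = 100,
) -> list[EvalResult]:
    """Score every roster method on the same replicates.

    ``selected`` holds (fst_table, qtl_table) pairs; ``null`` holds fst
    tables from unselected replicates.  Each method derives its own
    threshold from the null replicates, then detections and false positives
    are averaged over the selected replicates.
    """
    if not null:
        raise ValueError("uncalibrated method: no null replicates supplied")
    results = []
    n_qtl_total = int(len(selected[0][1])) if selected else 0
    for method in roster:
        maxima = [
            float(method_windows(method, f, criterion, resolution_bp)["STAT"].max())
            for f in null
        ]
        thr = null_threshold(maxima, quantile)
        det, fps = [], []
        for fst, qtl in selected:
            wins = method_windows(method, fst, criterion, resolution_bp)
            sig = wins[wins["STAT"] > thr.threshold]
            d, f = classify(sig, qtl, radius_cm=radius_cm, cm_per_bp=cm_per_bp)
            det.append(d)
            fps.append(f)
        mean_d = float(np.mean(det))
        mean_f = float(np.mean(fps))
        ratio = mean_d / mean_f if mean_f > 0 else float("inf")
        results.append(
            EvalResult(
                method=method,
                mean_detected=mean_d,
                mean_false_positives=mean_f,
                ratio=ratio,
                threshold=thr.threshold,
                n_qtl_total=n_qtl_total,
            )
        )
    return results


def run_benchmark(
    config: SimConfig,
    n_selected: int = 20,
    n_null: int = 10,
    roster: list[str] | None = None,
    pool_spec: PoolSpec | None = None,
    base_seed: int = 0,
    quantile: float = 0.95,
    radius_cm: float = 5.0,
    criterion: str = "gcv",
    resolution_bp: int = 100,
) -> list[EvalResult]:
    """Simulate replicates and produce the method-comparison table.

    Selected replicates use seeds base_seed..base_seed+n_selected-1; null
    replicates continue the seed sequence.  Every replicate goes through
    pooled sampling and per-marker FST before windowing.
    """
    roster = roster or ["spline", "distinct-25"]
    pool_spec = pool_spec or PoolSpec()
    cm_per_bp = config.chrom_cm / config.chrom_bp

    def prep(rep: SimReplicate, seed: int) -> pd.DataFrame:
        pooled = emit_pooled_dataset(rep, pool_spec, rng=np.random.default_rng(seed))
        return fst_table(pooled)

    selected = []
    for i in range(n_selected):
        s = base_seed + i
        rep = simulate_replicate(config.with_mode("truncation"), seed=s)
        selected.append((prep(rep, s + 500_000), rep.qtl))
    null = []
    for i in range(n_null):
        s = base_seed + n_selected + i
        rep = simulate_replicate(config.with_mode("random"), seed=s)
        null.append(prep(rep, s + 500_000))
    return compare_methods(
        selected,
        null,
        roster,
        cm_per_bp=cm_per_bp,
        radius_cm=radius_cm,
        quantile=quantile,
        criterion=criterion,
        resolution_bp=resolution_bp,
    )


def _windows_frame(window_set) -> pd.DataFrame:
    if isinstance(window_set, WindowSet):
        return pd.DataFrame(
            {
                "CHROM": [w.chrom for w in window_set],
                "WindowStart": [w.start for w in window_set],
                "WindowStop": [w.stop for w in window_set],
                "Wstat": [w.w_stat for w in window_set],
            }
        )
    return window_set


def merge_outliers(flagged: pd.DataFrame, merge_bp: int = 5_000_000) -> list[OutlierRegion]:
    """Group flagged windows whose gap is < merge_bp into regions
    (per chromosome).  Idempotent: merging the merged regions is a no-op."""
    regions: list[OutlierRegion] = []
    for chrom, g in flagged.groupby("CHROM", sort=True):
        g = g.sort_values("WindowStart")
        cur: list[int] = []
        stop = None
        for i, row in enumerate(g.itertuples(index=False)):
            if stop is not None and row.WindowStart - stop >= merge_bp:
                sub = g.iloc[cur]
                regions.append(_region(str(chrom), sub))
                cur = []
            cur.append(i)
            stop = row.WindowStop if stop is None or row.WindowStop > stop else stop
        if cur:
            regions.append(_region(str(chrom), g.iloc[cur]))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _region(chrom: str, sub: pd.DataFrame) -> OutlierRegion:
    return OutlierRegion(
        chrom=chrom,
        start=int(sub["WindowStart"].min()),
        stop=int(sub["WindowStop"].max()),
        windows=sub.reset_index(drop=True),
        max_w=float(sub["Wstat"].max()) if "Wstat" in sub else float("nan"),
    )


def scan(
    window_set,
    outlier_q: float = 0.999,
    merge_bp: int = 5_000_000,
) -> list[OutlierRegion]:
    """Empirical outlier scan: flag windows with W above the ``outlier_q``
    empirical quantile of all W values, then merge flagged windows within
    ``merge_bp`` of one another into regions."""
    df = _windows_frame(window_set)
    w = df["Wstat"].to_numpy(float)
    thr = float(np.quantile(w, outlier_q, method="linear"))
    flagged = df[df["Wstat"] > thr]
    return merge_outliers(flagged, merge_bp=merge_bp)
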