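"""Spline-defined genomic windows and the W statistic.

The central idea: per-SNP values of a noisy statistic (e.g. FST) along one
chromosome are treated as realizations of a smooth underlying function.  A
penalized cubic smoothing spline is fitted to (position, value) pairs, the
smoothing parameter chosen by cross-validation; the inflection points of the
fitted curve (sign changes of its second derivative) become window
boundaries.  Every local maximum of the fit is concave-down, so peaks land
strictly inside windows instead of being split across them, and window sizes
adapt to the local signal-to-noise structure.

Windows of unequal size are compared through the t-like statistic

    W = (X_bar - mu) / sqrt(s^2 / n)

where ``X_bar`` is the window mean, ``mu`` and ``s^2`` the mean and sample
variance of the statistic over the whole analyzed dataset, and ``n`` the
number of SNPs in the window.  W is not t-distributed (markers are not
independent under drift); it is a scale that makes unequal windows
comparable so outliers can be ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from ._spline import PenalizedFit, select_lambda

__all__ = [
    "MarkerSeries",
    "SplineFit",
    "Window",
    "WindowSet",
    "fit_smoothing_spline",
    "find_inflection_points",
    "define_windows",
    "compute_w",
    "spline_analyze",
]


@dataclass(frozen=True)
class MarkerSeries:
    """Sorted per-SNP positions and values for a single chromosome.

    Positions are 1-based bp integers, strictly increasing; values must be
    finite.  Fitting a cubic smoothing spline additionally requires at
    least 4 markers (enforced by :func:`fit_smoothing_spline`).
    """

    chrom: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        val = np.asarray(self.values, dtype=np.float64)
        if pos.ndim != 1 or val.ndim != 1 or pos.size != val.size:
            raise ValueError("positions and values must be 1-D and equal length")
        if pos.size < 1:
            raise ValueError(f"empty marker series on {self.chrom}")
        d = np.diff(pos)
        if np.any(d == 0):
            raise ValueError(
                f"non-unique positions on {self.chrom}; deduplicate or jitter upstream"
            )
        if np.any(d < 0):
            raise ValueError(f"positions on {self.chrom} must be strictly increasing")
        if not np.all(np.isfinite(val)):
            raise ValueError(f"non-finite values on {self.chrom}")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class SplineFit:
    """A fitted smoothing spline, evaluable with derivatives on its domain."""

    lam: float
    domain: tuple[float, float]
    criterion: str
    criterion_value: float
    _spline: CubicSpline
    _fit: PenalizedFit = field(repr=False)

    def __call__(self, x) -> np.ndarray:
        return self._spline(x)

    def derivative(self, x, order: int = 1) -> np.ndarray:
        return self._spline(x, nu=order)

    @property
    def edf(self) -> float:
        """Effective degrees of freedom (trace of the smoother matrix)."""
        return self._fit.edf

    @property
    def fitted_values(self) -> np.ndarray:
        return self._fit.fitted


@dataclass(frozen=True)
class Window:
    """One half-open window [start, stop) with its summary statistics."""

    chrom: str
    start: int
    stop: int
    n: int
    mean_y: float
    w_stat: float


@dataclass(frozen=True)
class WindowSet:
    """Contiguous, non-overlapping windows tiling one chromosome."""

    windows: list[Window]
    grand_mean: float
    grand_var: float
    boundaries: np.ndarray

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def w_stats(self) -> np.ndarray:
        return np.array([w.w_stat for w in self.windows])


def fit_smoothing_spline(series: MarkerSeries, criterion: str = "gcv") -> SplineFit:
    """Fit the penalized cubic smoothing spline to a marker series.

    The fit minimizes ``sum (Y_i - f(t_i))^2 + lam * int f''^2`` with lam
    chosen to minimize the GCV (default) or exact leave-one-out CV score
    over a log-spaced grid with golden-section refinement.
    """
    if len(series) < 4:
        raise ValueError(
            f"insufficient data: {len(series)} markers on {series.chrom}, need >= 4"
        )
    x = series.positions.astype(np.float64)
    y = series.values
    lam, score, fit = select_lambda(x, y, criterion=criterion)
    spline = CubicSpline(x, fit.fitted, bc_type="natural")
    return SplineFit(
        lam=lam,
        domain=(float(x[0]), float(x[-1])),
        criterion=criterion.lower(),
        criterion_value=score,
        _spline=spline,
        _fit=fit,
    )


def find_inflection_points(fit: SplineFit, resolution_bp: int = 100) -> np.ndarray:
    """Boundary positions where the spline's second derivative changes sign.

    f'' is evaluated on the grid t_min, t_min + resolution, ..., t_max.  A
    boundary is emitted at the midpoint of each grid interval whose endpoint
    signs strictly differ.  Runs of (numerically) zero curvature are bridged:
    a plateau between opposite nonzero signs yields one boundary at the
    plateau midpoint; a plateau between equal signs yields none, so locally
    linear stretches do not spray spurious boundaries.
    """
    if resolution_bp < 1:
        raise ValueError("resolution_bp must be >= 1")
    lo, hi = fit.domain
    grid = np.arange(lo, hi + 0.5 * resolution_bp, resolution_bp, dtype=np.float64)
    if grid[-1] > hi:
        grid[-1] = hi
    d2 = fit.derivative(grid, order=2)

    # zero tolerance: relative to the largest observed curvature, with an
    # absolute floor below any curvature that could move the fitted values
    # visibly across the domain (flat/linear fits otherwise flip sign on
    # pure float noise)
    span = hi - lo
    floor = 1e-4 * (np.ptp(fit.fitted_values) + 1e-300) / span**2
    tol = max(1e-9 * np.max(np.abs(d2), initial=0.0), floor)
    sgn = np.zeros(grid.size, dtype=np.int8)
    sgn[d2 > tol] = 1
    sgn[d2 < -tol] = -1

    nz = np.nonzero(sgn)[0]
    if nz.size < 2:
        return np.array([], dtype=np.float64)
    flips = np.nonzero(sgn[nz[:-1]] != sgn[nz[1:]])[0]
    bounds = 0.5 * (grid[nz[flips]] + grid[nz[flips + 1]])
    interior = (bounds > lo) & (bounds < hi)
    return bounds[interior]


def compute_w(window_mean: float, n: int, grand_mean: float, grand_var: float) -> float:
    """W = (X_bar - mu) / sqrt(s^2 / n), the size-scaled window score."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if grand_var <= 0:
        raise ValueError("degenerate data: grand variance must be positive")
    return float((window_mean - grand_mean) / np.sqrt(grand_var / n))


def define_windows(
    series: MarkerSeries,
    boundaries,
    grand_mean: float | None = None,
    grand_var: float | None = None,
) -> WindowSet:
    """Partition the series at the given boundary positions.

    Boundaries must be sorted and strictly inside the series' span.  Each
    marker falls in exactly one half-open interval; intervals containing no
    marker are merged into their right neighbor (the last interval merges
    leftward), so every window has n >= 1.  ``grand_mean``/``grand_var``
    default to the moments of this series (one-chromosome analysis) but can
    be overridden with genome-wide values for multi-chromosome scans.
    """
    bounds = np.asarray(boundaries, dtype=np.float64)
    if bounds.size and np.any(np.diff(bounds) < 0):
        raise ValueError("invalid boundaries: must be sorted")
    pos = series.positions
    lo, hi = float(pos[0]), float(pos[-1])
    if bounds.size and (bounds[0] <= lo or bounds[-1] >= hi):
        raise ValueError("invalid boundaries: must lie strictly inside the series span")

    mu = float(np.mean(series.values)) if grand_mean is None else float(grand_mean)
    if grand_var is None:
        # exactly-constant (or single-marker) data is degenerate (W := 0),
        # not a tiny variance produced by summation rounding
        if len(series) < 2 or np.ptp(series.values) == 0:
            s2 = 0.0
        else:
            s2 = float(np.var(series.values, ddof=1))
    else:
        s2 = float(grand_var)
    if s2 < 0:
        raise ValueError("grand_var must be >= 0")

    # snap boundaries to integer bp (ceil: a marker sitting exactly on a
    # boundary starts the right-hand window); no integer position can fall
    # strictly between b and ceil(b), so assignment is unambiguous
    bounds_int = np.unique(np.ceil(bounds).astype(np.int64)) if bounds.size else (
        np.array([], dtype=np.int64)
    )
    bounds_int = bounds_int[(bounds_int > lo) & (bounds_int <= hi)]

    # merge empty intervals rightward: keep a boundary only if the interval
    # to its left (since the previously kept boundary) holds >= 1 marker; an
    # empty trailing interval merges leftward by dropping the last boundary
    kept: list[int] = []
    prev = 0
    for b in bounds_int:
        c = int(np.searchsorted(pos, b, side="left"))
        if c - prev > 0:
            kept.append(int(b))
            prev = c
    if kept and prev == len(series):
        kept.pop()
    retained = np.array(kept, dtype=np.int64)

    edges = np.concatenate(([int(lo)], retained, [int(hi) + 1]))
    idx = np.searchsorted(edges, pos, side="right") - 1
    counts = np.bincount(idx, minlength=edges.size - 1)
    assert np.all(counts >= 1), "empty window survived merging"
    assert int(counts.sum()) == len(series)

    sums = np.bincount(idx, weights=series.values, minlength=edges.size - 1)
    means = sums / counts

    windows = []
    for k in range(counts.size):
        n_k = int(counts[k])
        m_k = float(means[k])
        w = 0.0 if s2 == 0.0 else compute_w(m_k, n_k, mu, s2)
        windows.append(
            Window(
                chrom=series.chrom,
                start=int(edges[k]),
                stop=int(edges[k + 1]),
                n=n_k,
                mean_y=m_k,
                w_stat=w,
            )
        )
    return WindowSet(
        windows=windows,
        grand_mean=mu,
        grand_var=s2,
        boundaries=retained.astype(np.float64),
    )


def spline_analyze(
    series: MarkerSeries,
    criterion: str = "gcv",
    resolution_bp: int = 100,
    grand_mean: float | None = None,
    grand_var: float | None = None,
) -> WindowSet:
    """Fit spline -> find inflection points -> define windows.

    The package's main entry point for one chromosome of per-SNP data.
    """
    fit = fit_smoothing_spline(series, criterion=criterion)
    bounds = find_inflection_points(fit, resolution_bp=resolution_bp)
    return define_windows(series, bounds, grand_mean=grand_mean, grand_var=grand_var)
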