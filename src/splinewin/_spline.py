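"""Penalized cubic smoothing-spline solver with exact CV/GCV scores.

Solves, for knots ``x_1 < ... < x_n`` and observations ``y_i``,

    minimize  sum_i (y_i - f(x_i))^2  +  lam * int f''(x)^2 dx

over twice-differentiable f.  The minimizer is a natural cubic spline with
knots at the data points (Reinsch form).  Writing ``g_i = f(x_i)`` and
``gamma`` for the second derivatives at the interior knots,

    (R + lam * Q^T Q) gamma = Q^T y,      g = y - lam * Q gamma,

where Q (n x (n-2)) holds second-difference coefficients and R is the
tridiagonal Gram matrix of the natural-spline second-derivative basis.
``R + lam Q^T Q`` is symmetric positive-definite and pentadiagonal, so the
solve is O(n) via a banded Cholesky factorization.

The hat (influence) matrix is ``A = I - lam * Q B^{-1} Q^T`` with
``B = R + lam Q^T Q``.  Its diagonal — needed for exact leave-one-out CV and
GCV scores — only requires the central five bands of ``B^{-1}``, which are
recovered from the Cholesky factor by the Takahashi/Erisman–Tinney backward
recursion, also in O(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky_banded, cho_solve_banded


def _qr_bands(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (h, R_bands, QtQ_bands) for knot vector x.

    Bands are in symmetric upper-diagonal-ordered form with bandwidth 2:
    row 0 = superdiagonal offset 2, row 1 = offset 1, row 2 = main diagonal
    (scipy ``*_banded`` convention, ab[u + i - j, j]).
    """
    n = x.size
    h = np.diff(x)
    m = n - 2  # interior knots

    # R: tridiagonal, R[i,i] = (h_i + h_{i+1})/3, R[i,i+1] = h_{i+1}/6
    r = np.zeros((3, m))
    r[2] = (h[:-1] + h[1:]) / 3.0
    r[1, 1:] = h[1:-1] / 6.0

    # Q columns: Q[j,j] = 1/h_j, Q[j+1,j] = -1/h_j - 1/h_{j+1}, Q[j+2,j] = 1/h_{j+1}
    inv_h = 1.0 / h
    a = inv_h[:-1]            # Q[j, j]
    b = -inv_h[:-1] - inv_h[1:]  # Q[j+1, j]
    c = inv_h[1:]             # Q[j+2, j]

    qtq = np.zeros((3, m))
    qtq[2] = a * a + b * b + c * c
    qtq[1, 1:] = b[:-1] * a[1:] + c[:-1] * b[1:]
    qtq[0, 2:] = c[:-2] * a[2:]
    return h, r, qtq


def _qty(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Q^T y, i.e. scaled second differences of y."""
    h = np.diff(x)
    return (y[2:] - y[1:-1]) / h[1:] - (y[1:-1] - y[:-2]) / h[:-1]


def _ldl_banded(b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Banded Cholesky/LDL^T factors of a symmetric pentadiagonal matrix.

    Returns (cb, d, l1, l2): the upper Cholesky band matrix plus the LDL^T
    view of it (l1[i] = L[i+1, i], l2[i] = L[i+2, i]).  On breakdown —
    severe ill-conditioning at extreme penalties — retries with a growing
    relative diagonal ridge (1e-12 upward), a negligible perturbation on the
    equilibrated matrix.
    """
    m = b.shape[1]
    bb = b
    for ridge in (0.0, 1e-12, 1e-10, 1e-8, 1e-6, 1e-4):
        if ridge:
            bb = b.copy()
            bb[2] = b[2] * (1.0 + ridge)
        try:
            cb = cholesky_banded(bb, lower=False)
        except np.linalg.LinAlgError:
            continue
        diag_u = cb[2]
        d = diag_u * diag_u
        l1 = np.zeros(m)
        l2 = np.zeros(m)
        l1[: m - 1] = cb[1, 1:] / diag_u[: m - 1]
        l2[: m - 2] = cb[0, 2:] / diag_u[: m - 2]
        return cb, d, l1, l2
    raise np.linalg.LinAlgError("banded Cholesky failed even with ridge")


def _banded_inverse_bands(
    d: np.ndarray, l1: np.ndarray, l2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Central bands of B^{-1} from LDL^T factors.

    Returns (z0, z1, z2): the main diagonal and the first and second
    superdiagonals of B^{-1}, via the backward recursion

        Z[i,j] = delta_ij / d_i - sum_{k=i+1}^{i+2} L[k,i] Z[k,j],  j >= i,

    with symmetry supplying entries below the diagonal.
    """
    m = d.size
    z0 = np.zeros(m)
    z1 = np.zeros(m)  # z1[i] = Z[i, i+1]
    z2 = np.zeros(m)  # z2[i] = Z[i, i+2]

    for i in range(m - 1, -1, -1):
        # Z[i, i+2]
        if i + 2 < m:
            z2[i] = -(l1[i] * z1[i + 1] + l2[i] * z0[i + 2])
        # Z[i, i+1]
        if i + 1 < m:
            acc = l1[i] * z0[i + 1]
            if i + 2 < m:
                acc += l2[i] * z1[i + 1]
            z1[i] = -acc
        # Z[i, i]
        acc = 1.0 / d[i]
        if i + 1 < m:
            acc -= l1[i] * z1[i]
        if i + 2 < m:
            acc -= l2[i] * z2[i]
        z0[i] = acc
    return z0, z1, z2


@dataclass(frozen=True)
class PenalizedFit:
    """One penalized fit: fitted knot values plus influence diagnostics."""

    fitted: np.ndarray          # g = fitted values at the knots
    gamma: np.ndarray           # second derivatives at interior knots
    hat_diag: np.ndarray        # diag of the smoother matrix A(lam)
    edf: float                  # trace of A (effective degrees of freedom)
    rss: float
    gcv: float
    loocv: float


def solve_penalized(x: np.ndarray, y: np.ndarray, lam: float) -> PenalizedFit:
    """Fit the smoothing spline for one value of the penalty ``lam``."""
    n = x.size
    h, r, qtq = _qr_bands(x)
    b = r + lam * qtq

    # diagonal equilibration: B = S B' S with S = diag(sqrt(diag B)); keeps
    # the banded Cholesky stable across extreme lam and irregular spacing
    s = np.sqrt(b[2])
    beq = np.empty_like(b)
    beq[2] = 1.0
    beq[1] = 0.0
    beq[1, 1:] = b[1, 1:] / (s[:-1] * s[1:])
    beq[0] = 0.0
    beq[0, 2:] = b[0, 2:] / (s[:-2] * s[2:])
    cb, d, l1, l2 = _ldl_banded(beq)
    gamma = cho_solve_banded((cb, False), _qty(x, y) / s) / s

    # g = y - lam * Q gamma  (Q gamma expanded column-wise)
    qg = np.zeros(n)
    inv_h = 1.0 / h
    qg[:-2] += inv_h[:-1] * gamma
    qg[1:-1] += (-inv_h[:-1] - inv_h[1:]) * gamma
    qg[2:] += inv_h[1:] * gamma
    g = y - lam * qg

    # bands of B^{-1} = S^{-1} B'^{-1} S^{-1}
    z0, z1, z2 = _banded_inverse_bands(d, l1, l2)
    m_ = z0.size
    z0 /= s * s
    if m_ > 1:
        z1[: m_ - 1] /= s[:-1] * s[1:]
    if m_ > 2:
        z2[: m_ - 2] /= s[:-2] * s[2:]

    # diag(Q Z Q^T): row i of Q touches columns i-2, i-1, i
    a0 = np.zeros(n)  # Q[i, i]
    a1 = np.zeros(n)  # Q[i, i-1]
    a2 = np.zeros(n)  # Q[i, i-2]
    m = n - 2
    a0[:m] = inv_h[:-1]
    a1[1 : m + 1] = -inv_h[:-1] - inv_h[1:]
    a2[2:] = inv_h[1:]

    def zpad(z: np.ndarray) -> np.ndarray:
        out = np.zeros(n)
        out[: z.size] = z
        return out

    p0, p1, p2 = zpad(z0), zpad(z1), zpad(z2)
    i = np.arange(n)
    im1 = np.maximum(i - 1, 0)
    im2 = np.maximum(i - 2, 0)
    diag_qzq = (
        a0 * a0 * p0[i]
        + a1 * a1 * p0[im1]
        + a2 * a2 * p0[im2]
        + 2.0 * a0 * a1 * p1[im1]
        + 2.0 * a1 * a2 * p1[im2]
        + 2.0 * a0 * a2 * p2[im2]
    )
    hat_diag = 1.0 - lam * diag_qzq
    edf = float(np.sum(hat_diag))

    resid = y - g
    rss = float(resid @ resid)
    denom = max(n - edf, 1e-12)
    gcv = n * rss / denom**2
    one_minus = np.clip(1.0 - hat_diag, 1e-12, None)
    loocv = float(np.mean((resid / one_minus) ** 2))
    return PenalizedFit(g, gamma, hat_diag, edf, rss, gcv, loocv)


def default_lambda_grid(x: np.ndarray, num: int = 50) -> np.ndarray:
    """Log-spaced penalty candidates scaled to the knot spacing.

    The penalty term scales like ``lam / h^3`` relative to the residual term,
    so candidates are anchored at the cube of the mean spacing and span 16
    orders of magnitude around it.
    """
    s = float(np.mean(np.diff(x)))
    return np.geomspace(s**3 * 1e-6, s**3 * 1e10, num)


def select_lambda(
    x: np.ndarray,
    y: np.ndarray,
    criterion: str = "gcv",
    grid: np.ndarray | None = None,
    refine_iters: int = 16,
) -> tuple[float, float, PenalizedFit]:
    """Choose lam by grid search + golden-section refinement in log space.

    Returns (lam, score, fit).  ``criterion`` is ``"gcv"`` or ``"cv"``
    (exact leave-one-out).  CV/GCV profiles need not be convex, so the grid
    locates the basin and golden-section only polishes within it.
    """
    crit = criterion.lower()
    if crit not in ("cv", "gcv"):
        raise ValueError(f"criterion must be 'cv' or 'gcv', got {criterion!r}")
    if grid is None:
        grid = default_lambda_grid(x)

    cache: dict[float, PenalizedFit] = {}

    def score(lam: float) -> float:
        if lam not in cache:
            cache[lam] = solve_penalized(x, y, lam)
        f = cache[lam]
        return f.gcv if crit == "gcv" else f.loocv

    scores = np.array([score(l) for l in grid])
    k = int(np.argmin(scores))
    lo = np.log(grid[max(k - 1, 0)])
    hi = np.log(grid[min(k + 1, grid.size - 1)])

    if hi > lo:
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = score(float(np.exp(c))), score(float(np.exp(d)))
        for _ in range(refine_iters):
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = score(float(np.exp(c)))
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = score(float(np.exp(d)))
        lam_ref = float(np.exp((a + b) / 2.0))
        if score(lam_ref) < scores[k]:
            best = lam_ref
        else:
            best = float(grid[k])
    else:
        best = float(grid[k])

    return best, score(best), cache[best]
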