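"""Independent reference fitters used to cross-check the IRLS routines.

These use variable projection: for a fixed relaxation time the signal
models are linear in the remaining parameters, so the profiled residual sum
of squares can be scanned on a dense grid and refined with a bounded scalar
minimizer.  No shared code path with the package's joint nonlinear fits.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


def _profile_rss_ir(t1_star: float, t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Best (a, b) and RSS for fixed T1* in y = a − b·exp(−t/T1*)."""
    x = np.exp(-t / t1_star)
    A = np.stack([np.ones_like(t), -x], axis=1)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    a, b = coef
    rss = float(np.sum((A @ coef - y) ** 2))
    return a, b, rss


def grid_fit_t1_signed(t: np.ndarray, y: np.ndarray, lo=10.0, hi=5000.0, n_grid=400):
    """Dense grid + bounded refinement over T1*; returns (a, b, t1_star, t1)."""
    grid = np.geomspace(lo, hi, n_grid)
    rss = np.array([_profile_rss_ir(g, t, y)[2] for g in grid])
    k = int(np.argmin(rss))
    bracket_lo = grid[max(k - 1, 0)]
    bracket_hi = grid[min(k + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda g: _profile_rss_ir(g, t, y)[2],
        bounds=(bracket_lo, bracket_hi), method="bounded",
        options={"xatol": 1e-10},
    )
    t1s = float(res.x)
    a, b, _ = _profile_rss_ir(t1s, t, y)
    return float(a), float(b), t1s, float(t1s * (b / a - 1.0))


def grid_fit_t1_magnitude(t: np.ndarray, y_mag: np.ndarray):
    """Magnitude-data oracle: best polarity hypothesis over flip indices."""
    best = None
    for j in range(int(np.argmin(y_mag)) + 2):
        y = y_mag.copy()
        y[:j] *= -1.0
        a, b, t1s, t1 = grid_fit_t1_signed(t, y)
        _, _, rss = _profile_rss_ir(t1s, t, y)
        if best is None or rss < best[0]:
            best = (rss, a, b, t1s, t1)
    return best[1:]


def _profile_rss_t2(t2: float, t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Best (M0, c) and RSS for fixed T2 in y = M0·exp(−t/T2) + c."""
    x = np.exp(-t / t2)
    A = np.stack([x, np.ones_like(t)], axis=1)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    m0, c = coef
    rss = float(np.sum((A @ coef - y) ** 2))
    return m0, c, rss


def grid_fit_t2(t: np.ndarray, y: np.ndarray, lo=1.0, hi=500.0, n_grid=400):
    """Dense grid + bounded refinement over T2; returns (m0, t2, c)."""
    grid = np.geomspace(lo, hi, n_grid)
    rss = np.array([_profile_rss_t2(g, t, y)[2] for g in grid])
    k = int(np.argmin(rss))
    res = minimize_scalar(
        lambda g: _profile_rss_t2(g, t, y)[2],
        bounds=(grid[max(k - 1, 0)], grid[min(k + 1, n_grid - 1)]),
        method="bounded", options={"xatol": 1e-10},
    )
    t2 = float(res.x)
    m0, c, _ = _profile_rss_t2(t2, t, y)
    return float(m0), t2, float(c)
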