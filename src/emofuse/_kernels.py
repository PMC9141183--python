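"""Compiled inner loops for the O(n^2) nonlinear-dynamics estimators.

Sample/approximate entropy and the Rosenstein largest-Lyapunov estimator all
require all-pairs template comparisons over ~1280-sample windows; these loops
are JIT-compiled with numba so a full feature battery over thousands of
windows stays tractable on one core.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[float, float]:
    """Template-match counts (B at length m, A at length m+1), self-matches excluded.

    Chebyshev distance; counts are summed over ordered pairs i < j using the
    n - m templates common to both lengths.
    """
    n = x.shape[0]
    nt = n - m  # templates of length m+1 start at 0..nt-1; length-m use same range
    b = 0.0
    a = 0.0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                dk = abs(x[i + k] - x[j + k])
                if dk > d:
                    d = dk
            if d <= r:
                b += 1.0
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1.0
    return a, b


@njit(cache=True)
def apen_phi(x: np.ndarray, m: int, r: float) -> float:
    """Phi^m(r) = mean over i of ln(C_i^m(r)), self-matches included."""
    n = x.shape[0]
    nt = n - m + 1
    total = 0.0
    for i in range(nt):
        c = 0.0
        for j in range(nt):
            d = 0.0
            for k in range(m):
                dk = abs(x[i + k] - x[j + k])
                if dk > d:
                    d = dk
            if d <= r:
                c += 1.0
        total += np.log(c / nt)
    return total / nt


@njit(cache=True)
def rosenstein_divergence(x: np.ndarray, dim: int, delay: int, theiler: int,
                          n_steps: int) -> np.ndarray:
    """Mean log nearest-neighbor divergence curve for the Rosenstein method.

    Embeds ``x`` with the given dimension and delay, finds each point's
    nearest neighbor outside the Theiler exclusion window, and averages
    ln(separation) over the first ``n_steps`` forward iterations. Entries with
    no valid pair are returned as NaN.
    """
    n = x.shape[0]
    m_pts = n - (dim - 1) * delay
    if m_pts <= n_steps + 1:
        return np.full(n_steps + 1, np.nan)
    usable = m_pts - n_steps  # points that can be followed n_steps forward
    log_div = np.zeros(n_steps + 1)
    counts = np.zeros(n_steps + 1)
    for i in range(usable):
        best = 1e300
        best_j = -1
        for j in range(usable):
            if abs(i - j) <= theiler:
                continue
            d2 = 0.0
            for k in range(dim):
                dk = x[i + k * delay] - x[j + k * delay]
                d2 += dk * dk
            if d2 < best and d2 > 0.0:
                best = d2
                best_j = j
        if best_j < 0:
            continue
        for step in range(n_steps + 1):
            d2 = 0.0
            for k in range(dim):
                dk = x[i + step + k * delay] - x[best_j + step + k * delay]
                d2 += dk * dk
            if d2 > 0.0:
                log_div[step] += 0.5 * np.log(d2)
                counts[step] += 1.0
    out = np.full(n_steps + 1, np.nan)
    for step in range(n_steps + 1):
        if counts[step] > 0:
            out[step] = log_div[step] / counts[step]
    return out
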