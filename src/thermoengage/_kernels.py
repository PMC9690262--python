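"""Compiled inner loops for the Hampel filter and sample entropy.

These kernels are plain O(N·W) / O(N²) implementations of the exact same
arithmetic the naive reference routines in the test suite perform; tests
assert bit-exact agreement.  They exist only so the replicated simulation
suites run in reasonable time.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _median_sorted(s: np.ndarray) -> float:
    # median of an already sorted 1-D array, matching np.median's
    # mean-of-two-middles convention for even lengths
    n = s.size
    h = n // 2
    if n % 2 == 1:
        return s[h]
    return (s[h - 1] + s[h]) / 2.0


@njit(cache=True)
def _med_mad_slow(x: np.ndarray, lo: int, hi: int):
    w = np.sort(x[lo:hi].copy())
    med = _median_sorted(w)
    mad = _median_sorted(np.sort(np.abs(w - med)))
    return med, mad


@njit(cache=True)
def _lower_bound(buf: np.ndarray, size: int, v: float) -> int:
    lo, hi = 0, size
    while lo < hi:
        mid = (lo + hi) // 2
        if buf[mid] < v:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def hampel_scan(x: np.ndarray, half: int, n_sigma: float, mad_scale: float):
    """Centered-window Hampel scan with truncated (shrinking) edge windows.

    Returns (local_medians, outlier_flags).  Windows with zero MAD flag
    nothing (constant neighbourhoods are never outliers).

    Interior positions keep the window as a maintained sorted buffer;
    the MAD there is the exact window median of |w − median| obtained by
    two-pointer merging outward from the median (the window length is
    odd, so both median and MAD are order statistics of the window).
    Edge windows fall back to a direct sort.
    """
    n = x.size
    medians = np.empty(n)
    flags = np.zeros(n, dtype=np.bool_)
    w_len = 2 * half + 1

    if w_len > n:
        for i in range(n):
            lo = max(0, i - half)
            hi = min(n, i + half + 1)
            med, mad = _med_mad_slow(x, lo, hi)
            medians[i] = med
            sigma = mad_scale * mad
            if sigma > 0.0 and abs(x[i] - med) > n_sigma * sigma:
                flags[i] = True
        return medians, flags

    # truncated edge windows
    for i in range(half):
        med, mad = _med_mad_slow(x, 0, i + half + 1)
        medians[i] = med
        sigma = mad_scale * mad
        if sigma > 0.0 and abs(x[i] - med) > n_sigma * sigma:
            flags[i] = True
    for i in range(n - half, n):
        med, mad = _med_mad_slow(x, i - half, n)
        medians[i] = med
        sigma = mad_scale * mad
        if sigma > 0.0 and abs(x[i] - med) > n_sigma * sigma:
            flags[i] = True

    # interior: sorted sliding window
    buf = np.sort(x[0:w_len].copy())
    for i in range(half, n - half):
        if i > half:
            old = x[i - half - 1]
            new = x[i + half]
            pos = _lower_bound(buf, w_len, old)
            if new >= old:
                while pos + 1 < w_len and buf[pos + 1] < new:
                    buf[pos] = buf[pos + 1]
                    pos += 1
                buf[pos] = new
            else:
                while pos > 0 and buf[pos - 1] > new:
                    buf[pos] = buf[pos - 1]
                    pos -= 1
                buf[pos] = new
        med = buf[half]
        li = half - 1
        ri = half + 1
        mad = 0.0
        for _ in range(half):
            dl = med - buf[li] if li >= 0 else np.inf
            dr = buf[ri] - med if ri < w_len else np.inf
            if dl <= dr:
                mad = dl
                li -= 1
            else:
                mad = dr
                ri += 1
        medians[i] = med
        sigma = mad_scale * mad
        if sigma > 0.0 and abs(x[i] - med) > n_sigma * sigma:
            flags[i] = True
    return medians, flags


@njit(cache=True)
def sampen_counts(x: np.ndarray, m: int, tau: int, r: float):
    """Template-match counts at lengths m and m+1 under Chebyshev distance.

    Counts ordered pairs (both (i,j) and (j,i); self-matches excluded).
    Template i at length L is (x[i], x[i+tau], ..., x[i+(L-1)tau]) and the
    index i ranges over [0, N - L*tau) at each length.
    """
    n = x.size
    n_m = n - m * tau
    n_m1 = n - (m + 1) * tau
    b = 0
    a = 0
    for i in range(n_m):
        for j in range(i + 1, n_m):
            d = 0.0
            for k in range(m):
                dk = abs(x[i + k * tau] - x[j + k * tau])
                if dk > d:
                    d = dk
            if d <= r:
                b += 2
                if j < n_m1:
                    dk = abs(x[i + m * tau] - x[j + m * tau])
                    if dk > d:
                        d = dk
                    if d <= r:
                        a += 2
    return b, a
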