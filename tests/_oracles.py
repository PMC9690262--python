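"""Independent naive reference implementations used only by the tests.

Each oracle takes the slow, transparent route (explicit loops, full
enumeration, textbook formulas) so it shares no code with the package's
optimized implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps


def sampen_counts_oracle(x: np.ndarray, m: int, tau: int, r: float) -> tuple[int, int]:
    """Brute-force template-match counts at lengths m and m+1.

    Builds every delay vector explicitly and counts all ordered pairs
    (i, j), j != i, whose Chebyshev distance is <= r.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)

    def count(mm: int) -> int:
        n_t = n - mm * tau
        templates = np.array([[x[i + k * tau] for k in range(mm)] for i in range(n_t)])
        d = np.max(np.abs(templates[:, None, :] - templates[None, :, :]), axis=2)
        within = (d <= r).sum() - n_t  # remove the n_t self-matches
        return int(within)

    return count(m), count(m + 1)


def sampen_oracle(x: np.ndarray, m: int = 2, r_coefficient: float = 0.2, tau: int = 1) -> float:
    """Brute-force sample entropy with r = r_coefficient * SD(x)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return float("nan")
    r = r_coefficient * sd
    b, a = sampen_counts_oracle(x, m, tau, r)
    if b == 0 or a == 0:
        return float("nan")
    n_m = n - m * tau
    n_m1 = n - (m + 1) * tau
    u_m = b / (n_m * (n - (m + 1) * tau))
    u_m1 = a / (n_m1 * (n - (m + 2) * tau))
    return float(-math.log(u_m1 / u_m))


def hampel_oracle(x: np.ndarray, window: int, n_sigma: float = 2.0,
                  mad_scale: float = 1.4826) -> tuple[np.ndarray, int]:
    """Naive centered Hampel filter with truncated edge windows.

    ``window`` is the odd full window length in samples.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    half = window // 2
    out = x.copy()
    flagged = 0
    for i in range(n):
        w = x[max(0, i - half): min(n, i + half + 1)]
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        sigma = mad_scale * mad
        if sigma > 0 and abs(x[i] - med) > n_sigma * sigma:
            out[i] = med
            flagged += 1
    return out, flagged


def rm_anova_oracle(data: np.ndarray) -> tuple[float, float, float, float]:
    """Naive RM-ANOVA: explicit double-loop sums of squares and the
    Greenhouse–Geisser epsilon from eigenvalues of the contrast-space
    covariance.  Returns (F, epsilon, df1, df2)."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = data.sum() / data.size
    row_means = [sum(data[i, :]) / k for i in range(n)]
    col_means = [sum(data[:, j]) / n for j in range(k)]
    ss_subj = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_sess = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((data[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_subj - ss_sess
    f = (ss_sess / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))

    # epsilon via an orthonormal contrast basis (Helmert), eigenvalue form
    helmert = np.zeros((k - 1, k))
    for r in range(1, k):
        helmert[r - 1, :r] = 1.0
        helmert[r - 1, r] = -r
        helmert[r - 1] /= np.linalg.norm(helmert[r - 1])
    s = np.cov(data, rowvar=False, ddof=1)
    lam = np.linalg.eigvalsh(helmert @ s @ helmert.T)
    eps = (lam.sum() ** 2) / ((k - 1) * (lam**2).sum())
    eps = min(1.0, max(1.0 / (k - 1), eps))
    return f, eps, eps * (k - 1), eps * (k - 1) * (n - 1)


def wilcoxon_exact_enumeration(pre, post) -> tuple[float, float]:
    """Exact two-sided signed-rank p by explicitly enumerating all 2^n
    sign assignments (n small).  Returns (W_plus, p)."""
    d = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    tol = 1e-9
    p_le = np.mean(ws <= w_obs + tol)
    p_ge = np.mean(ws >= w_obs - tol)
    return float(w_obs), float(min(1.0, 2.0 * min(p_le, p_ge)))


def bh_oracle(p_values) -> np.ndarray:
    """Textbook Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return adj
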