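"""Longitudinal statistics for thermal features and clinical scores.

The workflow mirrors standard small-cohort repeated-measures practice:

* clinical pre/post scores: Shapiro–Wilk normality gate, then an exact
  Wilcoxon signed-rank test (the cohorts are far too small for the
  normal approximation to be trusted);
* thermal features (per ROI × metric): one-way repeated-measures ANOVA
  with the session as within-subject factor, Greenhouse–Geisser
  sphericity correction of the degrees of freedom, and — when the
  omnibus rejects — all pairwise paired t-tests with Benjamini–Hochberg
  FDR adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

SESSION_LABELS = {0: "T0", 1: "T1", 2: "T2"}


def _label(session: int) -> str:
    return SESSION_LABELS.get(session, f"T{session}")


# ---------------------------------------------------------------------------
# normality gate and Wilcoxon signed-rank


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk W and p, used as a gate between parametric and
    rank-based procedures.  Supported for 3 ≤ n ≤ 50."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 50:
        raise ValueError(f"shapiro_wilk supports 3 <= n <= 50, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("shapiro_wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


@dataclass(frozen=True)
class WilcoxonResult:
    w: float       # W+ : sum of ranks of positive differences
    z: float       # normal-approximation statistic (tie-corrected, no CC)
    p: float       # two-sided p-value (exact or approximate per `mode`)
    mode: str
    n: int         # pairs used after dropping zero differences


def _signed_rank_exact_p(dranks: np.ndarray, w2: int) -> float:
    """Exact two-sided p of W+ over all 2^n equiprobable sign assignments.

    ``dranks`` are doubled midranks (integers, so ties are exact);
    ``w2`` is the observed doubled W+.  The distribution is built by
    dynamic programming — mathematically identical to enumerating every
    sign assignment.
    """
    total = int(dranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in dranks:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    n_assign = 2.0 ** len(dranks)
    p_le = dist[: w2 + 1].sum() / n_assign
    p_ge = dist[w2:].sum() / n_assign
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(pre, post, mode: str = "auto") -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on post − pre differences.

    Zero differences are dropped before ranking; ties get midranks.
    ``mode`` is ``"exact"`` (sign-assignment distribution, n ≤ 25),
    ``"normal_approx"`` (z with tie-corrected σ, no continuity
    correction), or ``"auto"`` (exact when n ≤ 25).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D vectors of equal length")
    d = post - pre
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; Wilcoxon test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    sigma = math.sqrt(float((ranks**2).sum())) / 2.0
    z = (w_plus - mu) / sigma
    if mode == "auto":
        mode = "exact" if n <= 25 else "normal_approx"
    if mode == "exact":
        if n > 25:
            raise ValueError(f"exact mode supported for n <= 25, got n={n}")
        dranks = np.rint(2.0 * ranks).astype(np.int64)
        p = _signed_rank_exact_p(dranks, int(round(2.0 * w_plus)))
    elif mode == "normal_approx":
        p = 2.0 * sps.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return WilcoxonResult(w=w_plus, z=float(z), p=float(p), mode=mode, n=n)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with sphericity correction


@dataclass(frozen=True)
class RMAnovaResult:
    f: float
    df1: float          # ε-corrected numerator df: ε(k−1)
    df2: float          # ε-corrected denominator df: ε(k−1)(n−1)
    epsilon: float
    p: float
    n_complete: int
    k: int


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse–Geisser ε from the session sample-covariance matrix."""
    n, k = data.shape
    s = np.cov(data, rowvar=False, ddof=1)
    # double-center, then ε = tr(S̃)² / ((k−1)·ΣS̃²)
    s_dc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    num = np.trace(s_dc) ** 2
    den = (k - 1) * np.sum(s_dc**2)
    if den == 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova_matrix(data: np.ndarray, epsilon_method: str = "gg") -> RMAnovaResult:
    """One-way repeated-measures ANOVA on an n_subjects × k_sessions matrix.

    Partitions the total sum of squares into subject, session, and error
    components; ``F = MS_sessions / MS_error`` is tested at
    Greenhouse–Geisser-corrected degrees of freedom ``ε(k−1)`` and
    ``ε(k−1)(n−1)`` (``epsilon_method="hf"`` selects Huynh–Feldt).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be an n_subjects x k_sessions matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 sessions, got {n} x {k}")
    grand = data.mean()
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_sess = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_subj - ss_sess
    ms_sess = ss_sess / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_err <= 0:
        raise ValueError("zero error variance; RM-ANOVA undefined")
    f = ms_sess / ms_err
    eps = _gg_epsilon(data)
    if epsilon_method == "hf":
        num = n * (k - 1) * eps - 2
        den = (k - 1) * (n - 1 - (k - 1) * eps)
        eps = float(np.clip(num / den, 1.0 / (k - 1), 1.0)) if den > 0 else 1.0
    elif epsilon_method != "gg":
        raise ValueError(f"unknown epsilon_method {epsilon_method!r}")
    df1 = eps * (k - 1)
    df2 = eps * (k - 1) * (n - 1)
    p = float(sps.f.sf(f, df1, df2))
    return RMAnovaResult(float(f), float(df1), float(df2), float(eps), p, n, k)


def cohort_matrix(cohort: pd.DataFrame, roi: str, metric: str) -> tuple[np.ndarray, list[str]]:
    """Pivot the long cohort table into a complete-case subjects × sessions
    matrix (listwise deletion) for one ROI/metric cell."""
    cell = cohort[(cohort["roi"] == roi) & (cohort["metric"] == metric)]
    wide = cell.pivot_table(index="subject", columns="session", values="value", aggfunc="first")
    wide = wide.dropna(axis=0)
    return wide.to_numpy(dtype=float), list(wide.index)


def rm_anova(cohort: pd.DataFrame, roi: str, metric: str,
             epsilon_method: str = "gg") -> RMAnovaResult:
    """RM-ANOVA for one ROI/metric from the long cohort table; subjects
    missing any session are dropped listwise."""
    data, subjects = cohort_matrix(cohort, roi, metric)
    if len(subjects) < 2:
        raise ValueError(f"fewer than 2 complete subjects for {roi}/{metric}")
    return rm_anova_matrix(data, epsilon_method=epsilon_method)


# ---------------------------------------------------------------------------
# pairwise comparisons and FDR


@dataclass(frozen=True)
class PairwiseResult:
    comparison: str
    t: float
    p_raw: float
    p_adjusted: float = float("nan")


def paired_t_arrays(a, b) -> tuple[float, float]:
    """Paired t-test (n−1 df) on two matched vectors; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t needs >= 2 matched pairs")
    if np.ptp(a - b) == 0 and not np.any(a - b):
        return 0.0, 1.0
    if np.std(a - b, ddof=1) == 0:
        raise ValueError("zero-variance differences; paired t undefined")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def paired_t(cohort: pd.DataFrame, roi: str, metric: str,
             pair: tuple[int, int]) -> PairwiseResult:
    """Paired t-test between two sessions for one ROI/metric cell."""
    data, subjects = cohort_matrix(cohort, roi, metric)
    if len(subjects) < 2:
        raise ValueError(f"fewer than 2 complete subjects for {roi}/{metric}")
    i, j = pair
    t, p = paired_t_arrays(data[:, i], data[:, j])
    return PairwiseResult(f"{_label(i)} vs {_label(j)}", t, p)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


# ---------------------------------------------------------------------------
# clinical score deltas


def _round_half_up_1(x: float) -> float:
    """Round to 1 decimal, halves away from zero (printed-table convention)."""
    return math.copysign(math.floor(abs(x) * 10.0 + 0.5) / 10.0, x)


def clinical_deltas(records: pd.DataFrame) -> pd.DataFrame:
    """Add pre/post change columns to a clinical score table.

    Expects columns ``t0`` and ``t2``; appends ``delta = T2 − T0`` and
    ``delta_pct = 100·(T2 − T0)/T0``, both rounded to 1 decimal (halves
    away from zero).  Requires T0 > 0 for the percentage.
    """
    if not {"t0", "t2"}.issubset(records.columns):
        raise ValueError("clinical table must have columns 't0' and 't2'")
    t0 = records["t0"].to_numpy(dtype=float)
    t2 = records["t2"].to_numpy(dtype=float)
    if np.any(t0 <= 0):
        raise ValueError("delta_pct requires T0 > 0 for every record")
    out = records.copy()
    out["delta"] = [_round_half_up_1(d) for d in t2 - t0]
    out["delta_pct"] = [_round_half_up_1(p) for p in 100.0 * (t2 - t0) / t0]
    return out


# ---------------------------------------------------------------------------
# full report


@dataclass
class StatReport:
    """Machine-readable result of the full statistical workflow."""

    alpha: float
    omnibus: dict = field(default_factory=dict)       # (roi, metric) -> RMAnovaResult | error
    pairwise: dict = field(default_factory=dict)      # (roi, metric) -> [PairwiseResult]
    clinical: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"alpha": self.alpha, "omnibus": {}, "pairwise": {}, "clinical": self.clinical}
        for (roi, metric), res in self.omnibus.items():
            key = f"{roi}/{metric}"
            d["omnibus"][key] = res if isinstance(res, dict) else {
                "F": res.f, "df1": res.df1, "df2": res.df2,
                "epsilon": res.epsilon, "p": res.p, "n_complete": res.n_complete,
            }
        for (roi, metric), results in self.pairwise.items():
            d["pairwise"][f"{roi}/{metric}"] = [
                {"comparison": r.comparison, "t": r.t, "p_raw": r.p_raw,
                 "p_adjusted": r.p_adjusted}
                for r in results
            ]
        return d

    def to_markdown(self) -> str:
        """Pairwise summary table (ROI, Metric, Comparison, t, adjusted p)."""
        lines = [
            "| ROI | Metric | Comparison | t-Stat | Adjusted p-Value |",
            "| --- | --- | --- | --- | --- |",
        ]
        for (roi, metric), results in self.pairwise.items():
            for r in results:
                lines.append(
                    f"| {roi} | {metric} | {r.comparison} | {r.t:.3f} | {r.p_adjusted:.4f} |"
                )
        return "\n".join(lines)


def run_statistics(
    cohort: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    alpha: float = 0.05,
    epsilon_method: str = "gg",
) -> StatReport:
    """Run the full workflow over every (ROI, metric) cell of a cohort.

    Per cell: RM-ANOVA omnibus; when the corrected omnibus p < alpha,
    all pairwise session paired t-tests are run and FDR-adjusted as a
    family.  If a clinical table is supplied, its pre/post scores get
    the Shapiro–Wilk gate and the Wilcoxon signed-rank test.  Per-cell
    failures are recorded as flagged errors, never silently dropped.
    """
    report = StatReport(alpha=alpha)
    sessions = sorted(cohort["session"].unique())
    for roi in sorted(cohort["roi"].unique()):
        for metric in sorted(cohort[cohort["roi"] == roi]["metric"].unique()):
            try:
                res = rm_anova(cohort, roi, metric, epsilon_method=epsilon_method)
            except ValueError as exc:
                report.omnibus[(roi, metric)] = {"error": str(exc)}
                continue
            report.omnibus[(roi, metric)] = res
            if res.p < alpha:
                pairs = list(combinations(range(len(sessions)), 2))
                results = []
                for pair in pairs:
                    try:
                        results.append(paired_t(cohort, roi, metric, pair))
                    except ValueError as exc:
                        results.append(PairwiseResult(
                            f"{_label(pair[0])} vs {_label(pair[1])}",
                            float("nan"), float("nan")))
                ok = [i for i, r in enumerate(results) if not math.isnan(r.p_raw)]
                if ok:
                    adj = fdr_adjust([results[i].p_raw for i in ok])
                    for idx, a in zip(ok, adj):
                        r = results[idx]
                        results[idx] = PairwiseResult(r.comparison, r.t, r.p_raw, float(a))
                report.pairwise[(roi, metric)] = results
    if clinical is not None and len(clinical):
        try:
            d = clinical["t2"].to_numpy(float) - clinical["t0"].to_numpy(float)
            w_stat, w_p = shapiro_wilk(d)
            wres = wilcoxon_signed_rank(clinical["t0"], clinical["t2"])
            report.clinical = {
                "shapiro": {"W": w_stat, "p": w_p},
                "wilcoxon": {"W": wres.w, "z": wres.z, "p": wres.p,
                             "mode": wres.mode, "n": wres.n},
            }
        except ValueError as exc:
            report.clinical = {"error": str(exc)}
    return report
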