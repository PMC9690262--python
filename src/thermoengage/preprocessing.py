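"""Artifact repair for ROI temperature time courses.

Two stages, applied in this order:

1. :func:`repair_gaps` — samples flagged invalid by the ROI tracker
   (motion periods, e.g. a head rotation too wide to follow) are replaced,
   run by run, with the mean of the nearest valid samples flanking the run.
2. :func:`hampel_filter` — residual motion spikes are removed with a
   centered sliding-window Hampel filter: a sample deviating more than
   ``n_sigma`` robust standard deviations (1.4826·MAD) from the local
   median is replaced by that median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import hampel_scan
from .core import ThermalSeries


@dataclass(frozen=True)
class RepairParams:
    """Gap-repair settings: ``flank`` valid samples are averaged on each
    side of an invalid run (single-sided at the series edges)."""

    flank: int = 6

    def __post_init__(self) -> None:
        if self.flank < 1:
            raise ValueError(f"flank must be >= 1, got {self.flank}")


@dataclass(frozen=True)
class HampelParams:
    """Hampel filter settings.

    window_s
        Full width of the centered window, in seconds (default 15 s).
    n_sigma
        Rejection threshold in robust standard deviations (default 2).
    mad_scale
        Gaussian-consistency factor turning the MAD into a standard
        deviation estimate (default 1.4826).
    """

    window_s: float = 15.0
    n_sigma: float = 2.0
    mad_scale: float = 1.4826

    def __post_init__(self) -> None:
        if not self.window_s > 0:
            raise ValueError(f"window_s must be > 0, got {self.window_s}")
        if not self.n_sigma > 0:
            raise ValueError(f"n_sigma must be > 0, got {self.n_sigma}")


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of invalid samples as half-open [start, stop) pairs."""
    runs = []
    n = valid.size
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def repair_gaps(series: ThermalSeries, params: RepairParams = RepairParams()) -> ThermalSeries:
    """Replace tracking-failure gaps with flanking-sample means.

    Every maximal invalid run is replaced, each sample in the run, by the
    mean of the ``flank`` nearest valid samples before the run and the
    ``flank`` nearest valid samples after it; at the series edges only the
    available side contributes.  Valid samples are untouched and the
    returned mask is all-true.

    Raises
    ------
    ValueError
        If the series is fully invalid, or an invalid run has no valid
        neighbour on either side.
    """
    valid = series.valid
    if not valid.any():
        raise ValueError("cannot repair a fully-invalid series")
    if valid.all():
        return series.with_samples(series.samples.copy())

    x = series.samples.copy()
    valid_idx = np.flatnonzero(valid)
    for start, stop in _invalid_runs(valid):
        # nearest `flank` valid samples strictly before / after the run
        before = valid_idx[valid_idx < start][-params.flank:]
        after = valid_idx[valid_idx >= stop][: params.flank]
        neighbours = np.concatenate([before, after])
        if neighbours.size == 0:
            raise ValueError(f"invalid run [{start}, {stop}) has no valid neighbours")
        x[start:stop] = series.samples[neighbours].mean()
    return series.with_samples(x, valid=np.ones(series.n, dtype=bool))


def hampel_filter(
    series: ThermalSeries, params: HampelParams = HampelParams()
) -> tuple[ThermalSeries, int]:
    """Remove spike outliers with a centered Hampel filter.

    The window length in samples is ``round(window_s · sampling_rate)``,
    forced odd so the window is centered; edge windows shrink rather than
    pad.  Returns the filtered series and the number of replaced samples.
    Windows whose MAD is zero (locally constant signal) flag nothing.
    """
    x = series.samples
    w = int(round(params.window_s * series.sampling_rate))
    if w % 2 == 0:
        w += 1
    if w > series.n:
        warnings.warn(
            f"Hampel window ({w} samples) exceeds series length ({series.n}); "
            "using a single global window",
            stacklevel=2,
        )
        w = series.n if series.n % 2 == 1 else series.n - 1
        if w < 1:
            w = 1
    half = w // 2
    medians, flags = hampel_scan(np.ascontiguousarray(x, dtype=float), half,
                                 float(params.n_sigma), float(params.mad_scale))
    out = x.copy()
    out[flags] = medians[flags]
    return series.with_samples(out), int(flags.sum())


def preprocess(
    series: ThermalSeries,
    repair: RepairParams = RepairParams(),
    hampel: HampelParams = HampelParams(),
) -> tuple[ThermalSeries, dict]:
    """Full artifact-repair chain: gap repair, then Hampel filtering.

    Returns the cleaned series and a summary dict with the number of
    repaired samples, the repaired fraction, and the Hampel outlier count.
    """
    n_invalid = int((~series.valid).sum())
    repaired = repair_gaps(series, repair)
    filtered, n_outliers = hampel_filter(repaired, hampel)
    return filtered, {
        "n_repaired": n_invalid,
        "repaired_fraction": n_invalid / series.n,
        "n_hampel_outliers": n_outliers,
    }
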