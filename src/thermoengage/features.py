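"""Per-block thermal features: mean temperature, variability, complexity.

Each session is cut into its paradigm blocks (one active+rest cycle per
block) and three features are computed per block, then averaged across
blocks:

* ``MeanTemp`` — arithmetic mean of the block's temperatures (°C),
* ``STD`` — sample standard deviation (N−1 denominator, °C),
* ``SampEn`` — sample entropy, the negative natural log of the
  conditional probability that template subseries of length ``m`` that
  match pointwise within tolerance ``r`` still match at length ``m+1``.
  Lower values indicate a more regular, lower-complexity signal, a known
  correlate of sympathetic predominance in facial thermal time courses.

Template matching uses the Chebyshev (max-norm) distance with delay
``tau``; the tolerance is ``r = r_coefficient · SD`` of the analyzed
segment, so SampEn is invariant to offset and positive rescaling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kernels import sampen_counts
from .core import BlockParadigm, ThermalSeries

METRICS = ("mean_temp", "std_temp", "sampen")


@dataclass(frozen=True)
class SampEnParams:
    """Sample entropy parameters: embedding dimension ``m`` (default 2),
    tolerance coefficient ``r_coefficient`` (default 0.2, multiplying the
    segment SD), and delay ``tau`` in samples (default 1)."""

    m: int = 2
    r_coefficient: float = 0.2
    tau: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if not self.r_coefficient > 0:
            raise ValueError(f"r_coefficient must be > 0, got {self.r_coefficient}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")


def segment_blocks(series: ThermalSeries, paradigm: BlockParadigm = BlockParadigm()) -> list[np.ndarray]:
    """Cut a session series into its paradigm blocks.

    Returns ``n_blocks`` contiguous, non-overlapping segments of
    ``(active_s + rest_s) · rate`` samples each, starting at t = 0
    (half-open sample intervals).  Trailing samples beyond the paradigm
    are dropped with a warning; a too-short series is an error reporting
    the number of missing samples.
    """
    per_block = paradigm.block_samples(series.sampling_rate)
    needed = paradigm.n_blocks * per_block
    if series.n < needed:
        raise ValueError(
            f"series has {series.n} samples but the paradigm needs {needed} "
            f"({needed - series.n} missing)"
        )
    if series.n > needed:
        warnings.warn(
            f"series has {series.n - needed} trailing samples beyond the "
            f"{paradigm.n_blocks}-block paradigm; dropping them",
            stacklevel=2,
        )
    return [series.samples[b * per_block : (b + 1) * per_block] for b in range(paradigm.n_blocks)]


def mean_temp(segment: np.ndarray) -> float:
    """Arithmetic mean temperature of a segment (°C)."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("empty segment")
    return float(segment.mean())


def std_temp(segment: np.ndarray) -> float:
    """Sample standard deviation of a segment (N−1 denominator, °C)."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise ValueError(f"std_temp needs at least 2 samples, got {segment.size}")
    return float(segment.std(ddof=1))


def sample_entropy(segment: np.ndarray, params: SampEnParams = SampEnParams()) -> float:
    """Sample entropy of a segment, in nats.

    The tolerance is ``r = r_coefficient · SD(segment)``.  Undefined
    results are returned as NaN rather than ±inf: a constant segment
    (SD = 0, hence r = 0) and segments with zero template matches at
    length ``m`` or ``m+1`` are both undefined.
    """
    x = np.ascontiguousarray(segment, dtype=float)
    m, tau = params.m, params.tau
    if x.size <= (m + 1) * tau:
        raise ValueError(
            f"segment of {x.size} samples is too short for m={m}, tau={tau} "
            f"(needs > {(m + 1) * tau})"
        )
    sd = x.std(ddof=1)
    if sd == 0.0:
        return float("nan")  # constant segment: r = 0, entropy undefined
    r = params.r_coefficient * sd

    b, a = sampen_counts(x, m, tau, r)
    if b == 0 or a == 0:
        warnings.warn(
            f"sample_entropy undefined: {b} matches at length {m}, {a} at {m + 1}",
            stacklevel=2,
        )
        return float("nan")
    n = x.size
    n_m = n - m * tau
    n_m1 = n - (m + 1) * tau
    if n - (m + 2) * tau <= 0:
        return float("nan")
    u_m = b / (n_m * (n - (m + 1) * tau))
    u_m1 = a / (n_m1 * (n - (m + 2) * tau))
    return float(-math.log(u_m1 / u_m))


@dataclass
class FeatureRecord:
    """Per-block and block-averaged features of one session/ROI series."""

    subject: str
    session: int
    roi: str
    block_values: dict[str, list[float]] = field(default_factory=dict)
    averages: dict[str, float] = field(default_factory=dict)
    n_undefined: dict[str, int] = field(default_factory=dict)

    @property
    def n_blocks(self) -> int:
        return len(next(iter(self.block_values.values())))


def session_features(
    series: ThermalSeries,
    paradigm: BlockParadigm = BlockParadigm(),
    params: SampEnParams = SampEnParams(),
) -> FeatureRecord:
    """Compute all three features per block and their block averages.

    The session-level value of each metric is the unweighted mean across
    blocks; blocks where SampEn is undefined are excluded from its
    average (their count is recorded in ``n_undefined``).  If every block
    is undefined for a metric, that is an error.
    """
    segments = segment_blocks(series, paradigm)
    record = FeatureRecord(subject=series.subject, session=series.session, roi=series.roi)
    per_metric = {
        "mean_temp": [mean_temp(s) for s in segments],
        "std_temp": [std_temp(s) for s in segments],
        "sampen": [sample_entropy(s, params) for s in segments],
    }
    for metric, values in per_metric.items():
        arr = np.asarray(values, dtype=float)
        defined = arr[~np.isnan(arr)]
        if defined.size == 0:
            raise ValueError(f"all {len(values)} blocks undefined for metric {metric!r}")
        record.block_values[metric] = values
        record.averages[metric] = float(defined.mean())
        record.n_undefined[metric] = int(np.isnan(arr).sum())
    return record
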