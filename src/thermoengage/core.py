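"""Core containers for ROI temperature time courses and the block paradigm.

A recording session is a uniformly sampled temperature time course extracted
from a facial region of interest (ROI) of a thermal video, together with a
per-sample validity mask marking frames where ROI tracking failed.  The
experimental paradigm alternates active and rest phases in fixed-length
blocks; all per-session features are computed block-wise on this grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: ROI labels used throughout: the nose tip and the corrugator (forehead)
#: regions, both strongly modulated by sympathetic vasomotor activity.
KNOWN_ROIS = ("nose_tip", "corrugator")


@dataclass
class ThermalSeries:
    """A uniformly sampled ROI temperature time course.

    Parameters
    ----------
    samples
        Temperatures in °C, length ``N``.
    sampling_rate
        Sampling frequency in Hz (strictly positive).
    valid
        Boolean mask of length ``N``; ``False`` marks samples from frames
        where ROI tracking failed.  If omitted, all samples are valid.
    roi, subject, session
        Provenance labels carried through the pipeline.
    """

    samples: np.ndarray
    sampling_rate: float
    valid: np.ndarray | None = None
    roi: str = "nose_tip"
    subject: str = "s0"
    session: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.valid is None:
            self.valid = np.ones(self.samples.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.samples.shape:
                raise ValueError(
                    f"valid mask length {self.valid.size} != samples length {self.samples.size}"
                )
        if not np.all(np.isfinite(self.samples[self.valid])):
            raise ValueError("temperatures must be finite where flagged valid")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at t=0."""
        return np.arange(self.n) / self.sampling_rate

    @property
    def invalid_fraction(self) -> float:
        return float(1.0 - self.valid.mean())

    def with_samples(self, samples: np.ndarray, valid: np.ndarray | None = None) -> "ThermalSeries":
        """Copy carrying provenance, with new samples (and optionally mask)."""
        return replace(
            self,
            samples=np.asarray(samples, dtype=float),
            valid=self.valid.copy() if valid is None else np.asarray(valid, dtype=bool),
        )


@dataclass(frozen=True)
class BlockParadigm:
    """Active/rest block timing grid of the training session.

    Defaults follow the standard protocol: ten blocks of 30 s active
    walking followed by 30 s rest.
    """

    n_blocks: int = 10
    active_s: float = 30.0
    rest_s: float = 30.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {self.n_blocks}")
        if not (self.active_s > 0 and self.rest_s > 0):
            raise ValueError("active_s and rest_s must be > 0")

    @property
    def block_s(self) -> float:
        return self.active_s + self.rest_s

    @property
    def total_s(self) -> float:
        return self.n_blocks * self.block_s

    def n_samples(self, sampling_rate: float) -> int:
        """Exact paradigm length in samples at the given rate."""
        return int(round(self.n_blocks * self.block_s * sampling_rate))

    def block_samples(self, sampling_rate: float) -> int:
        return int(round(self.block_s * sampling_rate))


@dataclass
class ROIMask:
    """Boolean pixel-membership mask of a region of interest.

    The mask is static across frames (tracking is external; per-frame
    validity flags travel with the series instead).  Row-major, 0-based
    pixel indexing.
    """

    mask: np.ndarray
    roi: str = "nose_tip"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D boolean matrix")
        if not self.mask.any():
            raise ValueError("mask must contain at least one member pixel")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())
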