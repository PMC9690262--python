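"""Synthetic thermal data with known ground truth.

Real facial-thermography recordings of the target population are not
publicly distributable, so validation rests on a generator that emulates
the statistical structure the analysis assumes:

* a 10-block active/rest paradigm sampled at 10 Hz (600 s per session),
* a slow baseline drift across sessions (negative drift = sympathetic
  cooling of the skin),
* physiological noise modelled as an AR(1)-plus-white mixture whose
  high-frequency weight can decay across sessions, driving sample
  entropy down independently of the mean level,
* spike outliers (motion residuals) and contiguous tracking-failure
  gaps covering a configurable fraction of frames (default 12%).

Every cell (subject, session, ROI) draws from its own substream derived
from the single global seed, so cohorts are reproducible and cells are
independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .core import KNOWN_ROIS, BlockParadigm, ROIMask, ThermalSeries

#: typical resting skin temperature by ROI (°C)
DEFAULT_BASELINES = {"nose_tip": 34.0, "corrugator": 35.5}


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration.

    The paradigm fields (10 blocks of 30 s + 30 s at 10 Hz) mirror the
    experimental protocol; ``gap_rate`` defaults to the 12% of frames the
    protocol typically needs corrected.  ``drift_per_session`` shifts the
    session mean (°C per session step); ``complexity_decay`` scales down
    the high-frequency noise weight per session step, lowering SampEn
    without changing the total noise variance.
    """

    seed: int = 0
    n_subjects: int = 5
    n_sessions: int = 3
    sampling_rate: float = 10.0
    n_blocks: int = 10
    active_s: float = 30.0
    rest_s: float = 30.0
    baseline_temp: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    noise_sd: float = 0.1
    drift_per_session: float = 0.0
    complexity_decay: float = 0.0
    outlier_rate: float = 0.0
    gap_rate: float = 0.12
    gap_len_s: float = 2.0
    # secondary knobs
    subject_sd: float = 0.3        # SD of subject-level baseline intercepts (°C)
    ar_phi: float = 0.97           # AR(1) pole of the slow vasomotor component
    hf_weight: float = 0.5         # high-frequency (white) variance weight at session 0
    outlier_amp_c: float = 2.0     # spike amplitude scale (°C)
    activity_amp_c: float = 0.0    # additive shift during active phases (°C)

    def __post_init__(self) -> None:
        checks = {
            "sampling_rate": self.sampling_rate > 0,
            "n_subjects": self.n_subjects >= 1,
            "n_sessions": self.n_sessions >= 1,
            "n_blocks": self.n_blocks >= 1,
            "active_s": self.active_s > 0,
            "rest_s": self.rest_s > 0,
            "noise_sd": self.noise_sd >= 0,
            "outlier_rate": 0 <= self.outlier_rate < 1,
            "gap_rate": 0 <= self.gap_rate < 1,
            "gap_len_s": self.gap_len_s > 0,
            "subject_sd": self.subject_sd >= 0,
            "ar_phi": 0 <= self.ar_phi < 1,
            "hf_weight": 0 <= self.hf_weight <= 1,
        }
        for name, ok in checks.items():
            if not ok:
                raise ValueError(f"invalid SynthConfig field {name!r}: {getattr(self, name)}")

    @property
    def paradigm(self) -> BlockParadigm:
        return BlockParadigm(self.n_blocks, self.active_s, self.rest_s)

    @property
    def n_samples(self) -> int:
        return self.paradigm.n_samples(self.sampling_rate)

    def hf_weight_at(self, session: int) -> float:
        """High-frequency variance weight for a session (clipped to [0, 1])."""
        return float(np.clip(self.hf_weight * (1.0 - self.complexity_decay * session), 0.0, 1.0))


@dataclass
class GroundTruth:
    """What the generator actually injected into one series."""

    session_mean_shift: float          # °C added to the ROI baseline
    complexity_level: float            # realized high-frequency weight
    outlier_idx: np.ndarray            # sample indices of injected spikes
    gap_idx: np.ndarray                # sample indices flagged invalid
    subject_offset: float = 0.0


def _cell_rng(config: SynthConfig, subject: str, session: int, roi: str) -> np.random.Generator:
    key = zlib.crc32(f"{subject}/{session}/{roi}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((config.seed, key)))


def _subject_rng(config: SynthConfig, subject: str) -> np.random.Generator:
    key = zlib.crc32(f"subject-intercept/{subject}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((config.seed, key)))


def _unit_noise(rng: np.random.Generator, n: int, phi: float, hf_w: float) -> np.ndarray:
    """Zero-mean, unit-variance AR(1)+white mixture with white weight hf_w."""
    if n == 0:
        return np.zeros(0)
    ar = lfilter([1.0], [1.0, -phi], rng.standard_normal(n)) * np.sqrt(1.0 - phi**2)
    white = rng.standard_normal(n)
    return np.sqrt(1.0 - hf_w) * ar + np.sqrt(hf_w) * white


def generate_roi_series(
    config: SynthConfig,
    subject: str = "s0",
    session: int = 0,
    roi: str = "nose_tip",
    subject_offset: float = 0.0,
) -> tuple[ThermalSeries, GroundTruth]:
    """Generate one session's ROI temperature series plus its ground truth.

    The clean signal is ``baseline + session·drift + subject_offset``
    plus the activity component and the noise mixture; spikes and
    contiguous invalid gaps are then overlaid.  Deterministic for a fixed
    config seed and cell identity.
    """
    if session >= config.n_sessions:
        raise ValueError(f"session {session} out of range (n_sessions={config.n_sessions})")
    if roi not in config.baseline_temp:
        raise ValueError(f"no baseline_temp entry for roi {roi!r}")
    rng = _cell_rng(config, subject, session, roi)
    n = config.n_samples
    shift = session * config.drift_per_session
    hf_w = config.hf_weight_at(session)

    x = np.full(n, config.baseline_temp[roi] + shift + subject_offset, dtype=float)
    if config.activity_amp_c != 0.0:
        t = np.arange(n) / config.sampling_rate
        active = (t % config.paradigm.block_s) < config.active_s
        x[active] += config.activity_amp_c
    if config.noise_sd > 0:
        x += config.noise_sd * _unit_noise(rng, n, config.ar_phi, hf_w)

    # motion-residual spikes
    outlier_idx = np.flatnonzero(rng.random(n) < config.outlier_rate)
    if outlier_idx.size:
        amp = config.outlier_amp_c * rng.uniform(0.5, 1.5, outlier_idx.size)
        x[outlier_idx] += rng.choice([-1.0, 1.0], outlier_idx.size) * amp

    # contiguous tracking-failure gaps (motion events)
    valid = np.ones(n, dtype=bool)
    gap_len = max(1, int(round(config.gap_len_s * config.sampling_rate)))
    n_runs = int(round(config.gap_rate * n / gap_len))
    placed = 0
    attempts = 0
    while placed < n_runs and attempts < 50 * max(n_runs, 1):
        attempts += 1
        start = int(rng.integers(0, n - gap_len + 1))
        if valid[max(0, start - 1) : min(n, start + gap_len + 1)].all():
            valid[start : start + gap_len] = False
            placed += 1
    gap_idx = np.flatnonzero(~valid)
    if gap_idx.size:  # corrupted values during tracking failure
        x[gap_idx] += rng.uniform(-3.0, 3.0, gap_idx.size)

    series = ThermalSeries(x, config.sampling_rate, valid, roi=roi,
                           subject=subject, session=session)
    truth = GroundTruth(shift, hf_w, outlier_idx, gap_idx, subject_offset)
    return series, truth


def generate_cohort(
    config: SynthConfig, rois: tuple[str, ...] = KNOWN_ROIS
) -> dict[tuple[str, int, str], tuple[ThermalSeries, GroundTruth]]:
    """Generate a full subjects × sessions × ROIs cohort.

    Session effects (drift, complexity decay) are identical across
    subjects; each subject additionally gets a random baseline intercept
    shared across sessions and ROIs.
    """
    if config.n_subjects < 2:
        raise ValueError(f"n_subjects must be >= 2 for a cohort, got {config.n_subjects}")
    cohort = {}
    for i in range(config.n_subjects):
        subject = f"s{i + 1:02d}"
        offset = float(config.subject_sd * _subject_rng(config, subject).standard_normal())
        for session in range(config.n_sessions):
            for roi in rois:
                cohort[(subject, session, roi)] = generate_roi_series(
                    config, subject, session, roi, subject_offset=offset
                )
    return cohort


def generate_clinical_scores(config: SynthConfig, improvement: float, score_noise: float = 0.5):
    """Paired pre/post clinical score table (e.g. a gross-motor scale).

    Pre-scores are uniform over a realistic range; the post-score adds a
    strictly positive, log-normally noise-scaled improvement, so any
    ``improvement > 0`` yields an all-positive-difference cohort.
    Returns a DataFrame with columns subject, t0, t2.
    """
    import pandas as pd

    if improvement < 0:
        raise ValueError(f"improvement must be >= 0, got {improvement}")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x5C0DE)))
    t0 = np.round(rng.uniform(10.0, 50.0, config.n_subjects), 2)
    delta = improvement * np.exp(score_noise * rng.standard_normal(config.n_subjects))
    t2 = np.round(t0 + delta, 2)
    return pd.DataFrame({
        "subject": [f"s{i + 1:02d}" for i in range(config.n_subjects)],
        "t0": t0,
        "t2": t2,
    })


@dataclass
class FrameStack:
    """A small synthetic thermal video: frames, per-ROI masks, validity
    flags, and the target per-ROI series each mask's mean reproduces."""

    frames: np.ndarray                      # (n_frames, H, W) float64 °C
    masks: dict[str, ROIMask]
    valid: np.ndarray                       # per-frame validity flags
    targets: dict[str, ThermalSeries]


def generate_frame_stack(
    config: SynthConfig,
    frame_shape: tuple[int, int] = (64, 64),
    subject: str = "s0",
    session: int = 0,
) -> FrameStack:
    """Generate a frame stack whose ROI means reproduce generated series.

    Every pixel inside an ROI mask carries exactly that frame's target
    temperature, so the masked mean equals the target series to floating
    point; the background is a static spatial gradient plus sensor noise.
    """
    h, w = frame_shape
    if h < 8 or w < 8:
        raise ValueError(f"frame_shape {frame_shape} too small for the ROI layout")
    layout = {  # fractional (row, col) boxes
        "corrugator": (0.10, 0.25, 0.35, 0.65),
        "nose_tip": (0.60, 0.45, 0.80, 0.60),
    }
    masks = {}
    for roi, (r0, c0, r1, c1) in layout.items():
        m = np.zeros((h, w), dtype=bool)
        m[int(r0 * h) : max(int(r0 * h) + 1, int(r1 * h)),
          int(c0 * w) : max(int(c0 * w) + 1, int(c1 * w))] = True
        masks[roi] = ROIMask(m, roi=roi)
    if (masks["corrugator"].mask & masks["nose_tip"].mask).any():
        raise ValueError("ROI layout overlaps at this frame shape")

    targets = {}
    valid = None
    for roi in layout:
        series, _ = generate_roi_series(config, subject, session, roi)
        targets[roi] = series
        valid = series.valid if valid is None else (valid & series.valid)
    n = next(iter(targets.values())).n

    rng = _cell_rng(config, subject, session, "frames")
    rows = np.linspace(30.0, 33.0, h)[:, None]
    background = rows + 0.2 * rng.standard_normal((h, w))
    frames = np.broadcast_to(background, (n, h, w)).copy()
    for roi, mask in masks.items():
        frames[:, mask.mask] = targets[roi].samples[:, None]
    return FrameStack(frames, masks, valid, targets)
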