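"""Reading and writing thermal series, frame stacks, and manifests.

Series travel as plain CSV (``time_s, temp_c, valid``) at a declared
uniform rate; frame stacks as multi-page 32-bit-float TIFF with a
companion mask TIFF; a manifest CSV binds subject/session/ROI to files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import ROIMask, ThermalSeries

SERIES_COLUMNS = ("time_s", "temp_c", "valid")


def write_series(series: ThermalSeries, path: str | Path) -> None:
    """Write a series as CSV with columns time_s, temp_c, valid."""
    df = pd.DataFrame({
        "time_s": series.times,
        "temp_c": series.samples,
        "valid": series.valid.astype(int),
    })
    df.to_csv(path, index=False, float_format="%.10g")


def read_series(
    path: str | Path,
    roi: str = "nose_tip",
    subject: str = "s0",
    session: int = 0,
    jitter_tol: float = 0.01,
) -> ThermalSeries:
    """Read a series CSV, inferring the sampling rate from the time axis.

    The time column must be monotonically increasing and uniform to
    within ``jitter_tol`` (relative to the median sampling interval).
    """
    df = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty series file")
    t = df["time_s"].to_numpy(dtype=float)
    if len(df) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path}: time column is not strictly increasing")
        step = float(np.median(dt))
        if np.any(np.abs(dt - step) > jitter_tol * step):
            raise ValueError(
                f"{path}: non-uniform timestamps (jitter beyond {jitter_tol:.0%} of "
                f"the {step:.6g} s median interval)"
            )
        rate = 1.0 / step
    else:
        rate = 1.0
    return ThermalSeries(
        df["temp_c"].to_numpy(dtype=float),
        rate,
        df["valid"].to_numpy().astype(bool),
        roi=roi,
        subject=subject,
        session=int(session),
    )


def extract_roi_timecourse(
    frames: np.ndarray,
    mask: ROIMask,
    validity: np.ndarray | None = None,
    sampling_rate: float = 10.0,
    **labels,
) -> ThermalSeries:
    """Average the masked pixels of every frame into a time course.

    Sample *i* is the arithmetic mean of the masked pixels of frame *i*;
    the validity flags (from the external ROI tracker) are copied onto
    the series unchanged.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError(f"frames must be (n, H, W), got shape {frames.shape}")
    if frames.shape[1:] != mask.mask.shape:
        raise ValueError(
            f"frame shape {frames.shape[1:]} does not match mask shape {mask.mask.shape}"
        )
    samples = frames[:, mask.mask].mean(axis=1)
    return ThermalSeries(samples, sampling_rate, validity, roi=mask.roi, **labels)


def write_frame_stack(frames: np.ndarray, path: str | Path) -> None:
    """Write frames as a multi-page float32 TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))


def read_frame_stack(path: str | Path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)


def write_mask(mask: ROIMask, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(path, mask.mask.astype(np.uint8))


def read_mask(path: str | Path, roi: str = "nose_tip") -> ROIMask:
    import tifffile

    return ROIMask(np.asarray(tifffile.imread(path)) > 0, roi=roi)


def write_manifest(rows: list[dict], path: str | Path) -> None:
    """Manifest CSV binding (subject, session, roi) to series files."""
    pd.DataFrame(rows, columns=["subject", "session", "roi", "path"]).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject", "session", "roi", "path") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    return df


def load_cohort_series(manifest_path: str | Path) -> list[ThermalSeries]:
    """Load every series referenced by a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    out = []
    for row in read_manifest(manifest_path).itertuples():
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        out.append(read_series(p, roi=row.roi, subject=str(row.subject), session=int(row.session)))
    return out
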