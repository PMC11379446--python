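"""Per-channel amplitude (RMS envelope) and spectral (AIF) features.

The envelope is the square root of a 500-ms centered moving average of
the squared signal (window truncated at the record edges), decimated to
the map frame rate.  The AIF — average instantaneous frequency — is the
power-weighted mean frequency (spectral centroid) of non-overlapping
500-ms Hann periodogram frames, restricted to the 20-450 Hz band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_types import AnalysisRegion, EMGRecording


@dataclass
class EnvelopeSeries:
    """RMS envelope frames: channels x frames (mV) at ``frame_rate`` Hz."""

    values: np.ndarray
    t: np.ndarray
    frame_rate: float

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class SpectralSeries:
    """Per-frame spectral centroid: channels x frames (Hz)."""

    aif: np.ndarray
    t: np.ndarray
    frame_s: float


def moving_rms(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Centered moving-RMS along the last axis, truncated at the edges."""
    w = int(round(window_s * fs))
    if w < 2:
        raise ValueError(f"window of {window_s:g} s spans fewer than 2 samples at fs={fs:g}")
    n = x.shape[-1]
    sq = np.square(x)
    csum = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(sq, axis=-1)], axis=-1
    )
    idx = np.arange(n)
    lo = np.clip(idx - w // 2, 0, n)
    hi = np.clip(idx - w // 2 + w, 0, n)
    sums = csum[..., hi] - csum[..., lo]
    counts = hi - lo
    return np.sqrt(sums / counts)


def rms_envelope(
    rec: EMGRecording, window_s: float = 0.5, frame_rate: float = 10.0
) -> EnvelopeSeries:
    """Smoothed RMS envelope of every channel, sampled at the map rate."""
    env = moving_rms(rec.signals, rec.fs, window_s)
    n_frames = int(np.floor(rec.duration_s * frame_rate))
    t_f = (np.arange(n_frames) + 0.5) / frame_rate
    idx = np.minimum((t_f * rec.fs).round().astype(int), rec.n_samples - 1)
    return EnvelopeSeries(values=env[:, idx], t=t_f, frame_rate=frame_rate)


def aif(
    rec: EMGRecording,
    frame_s: float = 0.5,
    band: tuple[float, float] = (20.0, 450.0),
) -> SpectralSeries:
    """Spectral centroid of non-overlapping Hann periodogram frames.

    Frames with (near) zero in-band power yield NaN.  The centroid is
    invariant to amplitude scaling of the signal.
    """
    frame_len = int(round(frame_s * rec.fs))
    if frame_len < 64:
        raise ValueError("AIF frames must contain at least 64 samples")
    n_frames = rec.n_samples // frame_len
    if n_frames == 0:
        raise ValueError("recording shorter than one AIF frame")
    x = rec.signals[:, : n_frames * frame_len].reshape(rec.n_channels, n_frames, frame_len)
    freqs, pxx = sps.periodogram(x, fs=rec.fs, window="hann", axis=-1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    f_band = freqs[sel]
    p_band = pxx[..., sel]
    power = p_band.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        centroid = (p_band @ f_band) / power
    centroid[~np.isfinite(centroid) | (power <= 0)] = np.nan
    t_f = (np.arange(n_frames) + 0.5) * frame_s
    return SpectralSeries(aif=centroid, t=t_f, frame_s=frame_s)


def _frame_sel(t: np.ndarray, start_s: float, end_s: float) -> np.ndarray:
    # half-open [start, end), matching RoATrajectory.slice
    return (t >= start_s - 1e-9) & (t < end_s - 1e-9)


def envelope_segment_mean(
    env: EnvelopeSeries,
    region: AnalysisRegion,
    good: np.ndarray | None = None,
) -> dict[str, float]:
    """Spatial-average envelope per segment (mean over good channels and
    frames inside each segment)."""
    if good is None:
        good = np.ones(env.n_channels, dtype=bool)
    if not good.any():
        raise ValueError("all channels marked bad; no envelope average possible")
    out: dict[str, float] = {}
    for seg in region:
        sel = _frame_sel(env.t, seg.start_s, seg.end_s)
        vals = env.values[np.ix_(good, sel)]
        out[seg.label] = float(np.nanmean(vals)) if vals.size else float("nan")
    return out


def aif_segment_mean(
    spec: SpectralSeries,
    region: AnalysisRegion,
    good: np.ndarray | None = None,
) -> dict[str, float]:
    """Grid-level AIF per segment: frames are averaged within each
    channel first, then across good channels (means commute only with
    equal frame counts, so the order is fixed and documented)."""
    if good is None:
        good = np.ones(spec.aif.shape[0], dtype=bool)
    if not good.any():
        raise ValueError("all channels marked bad; no AIF average possible")
    out: dict[str, float] = {}
    for seg in region:
        sel = _frame_sel(spec.t, seg.start_s, seg.end_s)
        vals = spec.aif[np.ix_(good, sel)]
        if vals.size == 0:
            out[seg.label] = float("nan")
            continue
        per_channel = np.nanmean(vals, axis=1)
        out[seg.label] = float(np.nanmean(per_channel))
    return out
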