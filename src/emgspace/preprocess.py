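"""Signal conditioning, contraction segmentation and endurance time.

Torque is low-passed (3rd-order Butterworth, 10 Hz) and used to segment
the record; EMG channels are band-passed 20-450 Hz (3rd order) with a
50 Hz notch.  All filters are applied forward-backward (zero phase) so
centroid timing is not skewed; the effective order therefore doubles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_types import AnalysisRegion, EMGRecording, Position, TorqueTrace

logger = logging.getLogger(__name__)


class SegmentationError(ValueError):
    """Raised when no usable contraction can be segmented."""


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filtering parameters for torque and EMG conditioning."""

    order: int = 3
    band: tuple[float, float] = (20.0, 450.0)
    notch_hz: float = 50.0
    notch_q: float = 30.0
    torque_lowpass_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band edges must satisfy 0 < low < high")


def filter_emg(rec: EMGRecording, spec: FilterSpec = FilterSpec()) -> EMGRecording:
    """Zero-phase bandpass + power-line notch on every channel.

    Removes DC by construction (the bandpass has no response at 0 Hz).
    """
    nyq = rec.fs / 2
    if spec.band[1] >= nyq:
        raise ValueError(
            f"bandpass upper edge {spec.band[1]:g} Hz not below Nyquist {nyq:g} Hz"
        )
    sos = sps.butter(spec.order, spec.band, btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.signals, axis=-1)
    if 0 < spec.notch_hz < nyq:
        b, a = sps.iirnotch(spec.notch_hz, spec.notch_q, fs=rec.fs)
        out = sps.filtfilt(b, a, out, axis=-1)
    return EMGRecording(signals=out, fs=rec.fs, layout=rec.layout,
                        channel_map=rec.channel_map)


def filter_torque(tq: TorqueTrace, spec: FilterSpec = FilterSpec()) -> TorqueTrace:
    """Zero-phase low-pass of the torque channel (unity DC gain)."""
    nyq = tq.fs / 2
    if spec.torque_lowpass_hz >= nyq:
        raise ValueError("torque low-pass cut-off not below Nyquist")
    sos = sps.butter(spec.order, spec.torque_lowpass_hz, btype="low", fs=tq.fs,
                     output="sos")
    out = sps.sosfiltfilt(sos, tq.torque)
    return TorqueTrace(torque=out, fs=tq.fs, mvt=tq.mvt,
                       target_fraction=tq.target_fraction)


def _channel_rms(x: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean(np.square(x), axis=-1))


def detect_bad_channels(
    rec: EMGRecording,
    snr_floor_db: float = 6.0,
    hold_window: tuple[float, float] | None = None,
    reference_window: tuple[float, float] | None = None,
) -> set[Position]:
    """Automated low-SNR channel screening.

    When a quasi-zero reference window is available, per-channel SNR is
    ``20 log10(rms_hold / rms_reference)`` and channels below
    ``snr_floor_db`` are flagged.  Without a reference the rule falls
    back to a robust amplitude outlier screen: channel RMS more than
    5 scaled-MAD above the grid median, or below 0.2x the median.
    Sidecar-declared bad channels (``layout.bad``) are always included.
    A warning is emitted if more than 20 % of channels end up flagged.
    """
    flagged: set[Position] = set(rec.layout.bad)
    n = rec.n_samples

    def _win(w: tuple[float, float]) -> np.ndarray:
        i0 = max(0, int(round(w[0] * rec.fs)))
        i1 = min(n, int(round(w[1] * rec.fs)))
        return rec.signals[:, i0:i1]

    if reference_window is not None and hold_window is not None:
        ref = _channel_rms(_win(reference_window))
        hold = _channel_rms(_win(hold_window))
        with np.errstate(divide="ignore", invalid="ignore"):
            snr_db = 20.0 * np.log10(hold / ref)
        low = ~np.isfinite(snr_db) | (snr_db < snr_floor_db)
        flagged |= {rec.channel_map[i] for i in np.nonzero(low)[0]}
    else:
        logger.info("no quasi-zero reference; falling back to robust RMS outlier rule")
        rms = _channel_rms(rec.signals)
        med = np.median(rms)
        mad = 1.4826 * np.median(np.abs(rms - med))
        out = (rms > med + 5.0 * mad) | (rms < 0.2 * med)
        flagged |= {rec.channel_map[i] for i in np.nonzero(out)[0]}

    if len(flagged) > 0.2 * rec.n_channels:
        warnings.warn(
            f"{len(flagged)} of {rec.n_channels} channels flagged bad (> 20 %); "
            "check electrode contact or the SNR threshold",
            stacklevel=2,
        )
    return flagged


def _first_sustained_below(
    torque: np.ndarray, fs: float, threshold: float, sustain_s: float
) -> int | None:
    """Index of the first sample opening a >= sustain_s run below threshold."""
    below = torque < threshold
    w = max(1, int(round(sustain_s * fs)))
    if below.size < w:
        return None
    # run[i] True iff below[i:i+w] is all True
    csum = np.concatenate(([0], np.cumsum(below)))
    runs = (csum[w:] - csum[:-w]) == w
    idx = np.nonzero(runs)[0]
    return int(idx[0]) if idx.size else None


@dataclass(frozen=True)
class EnduranceResult:
    """Endurance time relative to hold onset; censored if never failed."""

    endurance_s: float
    hold_onset_s: float
    failure_s: float
    censored: bool


def endurance_time(
    tq: TorqueTrace, drop_fraction: float = 0.5, sustain_s: float = 3.0
) -> EnduranceResult:
    """Time from hold onset until torque stays below drop_fraction x MVT.

    Failure is the first instant t* with torque < threshold throughout
    [t*, t* + sustain_s]; brief dips recover.  If the record ends before
    any sustained drop the result is censored at end of record.
    """
    if tq.mvt <= 0:
        raise ValueError("MVT must be positive")
    target = tq.target_fraction * tq.mvt
    onset_idx = np.nonzero(tq.torque >= 0.99 * target)[0]
    if onset_idx.size == 0:
        raise SegmentationError("no contraction detected: torque never reaches the target")
    hold_onset = onset_idx[0] / tq.fs

    thr = drop_fraction * tq.mvt
    start = int(onset_idx[0])
    fail = _first_sustained_below(tq.torque[start:], tq.fs, thr, sustain_s)
    if fail is None:
        end = tq.duration_s
        return EnduranceResult(end - hold_onset, hold_onset, end, censored=True)
    failure = (start + fail) / tq.fs
    return EnduranceResult(failure - hold_onset, hold_onset, failure, censored=False)


def segment_contraction(
    tq: TorqueTrace,
    quasi_zero_s: float = 4.0,
    segment_length_s: float = 10.0,
    mark_fraction: float = 0.5,
    sustain_s: float = 3.0,
    marks: tuple[float, float] | None = None,
) -> AnalysisRegion:
    """Bound the analysis region between the two quasi-zero windows.

    Transient marks are placed automatically at the torque crossings of
    ``mark_fraction x MVT`` (first crossing on the ascent; last sample
    above it before sustained task failure on the descent); manually
    provided ``marks`` (ascent_s, descent_s) take precedence.  Each mark
    is surrounded by a quasi-zero window of total length ``quasi_zero_s``
    and the region is the interval strictly between the two windows.
    T1/T2/T3 tile the region per :class:`AnalysisRegion`.
    """
    half = quasi_zero_s / 2
    if marks is not None:
        t_asc, t_desc = marks
    else:
        thr = mark_fraction * tq.mvt
        above = np.nonzero(tq.torque >= thr)[0]
        if above.size == 0:
            raise SegmentationError("no contraction detected: torque never crosses the mark level")
        t_asc = above[0] / tq.fs
        fail = _first_sustained_below(tq.torque[above[0]:], tq.fs, thr, sustain_s)
        if fail is None:
            t_desc = above[-1] / tq.fs
        else:
            fail_idx = above[0] + fail
            pre = above[above < fail_idx]
            t_desc = (pre[-1] if pre.size else above[0]) / tq.fs

    start = t_asc + half
    end = t_desc - half
    if end - start < segment_length_s:
        raise SegmentationError(
            f"analysis region {end - start:.2f} s shorter than one "
            f"{segment_length_s:g}-s segment"
        )
    if end - start < 3 * segment_length_s:
        warnings.warn(
            f"analysis region {end - start:.2f} s shorter than three segments; "
            "T1/T2/T3 will overlap",
            stacklevel=2,
        )
    qz = ((t_asc - half, t_asc + half), (t_desc - half, t_desc + half))
    return AnalysisRegion.from_bounds(start, end, segment_length_s, quasi_zero=qz)


def torque_segment_stats(
    tq: TorqueTrace, region: AnalysisRegion
) -> dict[str, tuple[float, float]]:
    """Per-segment (mean, CoV) of MVT-normalised torque.

    CoV uses the population standard deviation; a near-zero segment mean
    makes the CoV undefined (NaN).
    """
    out: dict[str, tuple[float, float]] = {}
    for seg in region:
        i0 = int(round(seg.start_s * tq.fs))
        i1 = int(round(seg.end_s * tq.fs))
        x = tq.torque[i0:i1] / tq.mvt
        if x.size == 0:
            out[seg.label] = (float("nan"), float("nan"))
            continue
        mean = float(x.mean())
        cov = float(x.std(ddof=0) / mean) if abs(mean) > 1e-12 else float("nan")
        out[seg.label] = (mean, cov)
    return out
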