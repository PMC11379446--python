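"""Sway-style spatial metrics of the activation-centroid trajectory.

The metric suite transplants the classical center-of-pressure (CoP)
posturography statistics onto the RoA trajectory (u, v) = (ft, fp)
within one analysis segment of N samples and duration T:

=====================  ==========================================  ========
metric                 definition                                  CoP analog
=====================  ==========================================  ========
AID (mm)               mean resultant distance from a reference    MDIST
AIP (mm)               total path length                           TOTEX
AIV (mm/s)             AIP / T                                     MVELO
AIS (mm)               RMS distance from the segment mean          RDIST
AEZ (mm^2)             95 % confidence ellipse area                AREA-CE
ACZ (mm^2)             95 % confidence circle area                 AREA-CC
AMZ (mm^2/s)           area swept about the mean per unit time     AREA-SW
=====================  ==========================================  ========

Each metric also has per-direction variants (FT = fiber-transverse,
FP = fiber-parallel).  The AID family is referenced, by default, to the
centroid's position at the start of the analysis region (mean over the
first second) so it reads as "displacement from the initial position";
the strict posturographic alternative (per-segment mean reference) is
available via ``MetricConfig.reference_policy``.  Spread and area
metrics are always mean-centered within the segment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .core_types import (
    AnalysisRegion,
    RoATrajectory,
    SegmentMetrics,
    TorqueTrace,
)
from .features import EnvelopeSeries, SpectralSeries, aif_segment_mean, envelope_segment_mean
from .preprocess import torque_segment_stats


@dataclass(frozen=True)
class MetricConfig:
    """Tunables of the spatial-metric suite.

    ``reference_policy``: "baseline" references the AID family to the
    mean centroid over the first ``baseline_s`` seconds of the analysis
    region; "window_mean" uses each segment's own mean (the strict CoP
    convention).  ``circle_z`` = 1.645 is the one-sided 95 % normal
    quantile of the confidence-circle construction.  Segments whose
    valid frames leave a gap longer than ``max_gap_s`` get NaN path
    metrics (path length is inflated by bridging gaps).
    """

    reference_policy: str = "baseline"
    baseline_s: float = 1.0
    ellipse_confidence: float = 0.95
    circle_z: float = 1.645
    max_gap_s: float = 1.0

    def __post_init__(self) -> None:
        if self.reference_policy not in ("baseline", "window_mean"):
            raise ValueError("reference_policy must be 'baseline' or 'window_mean'")
        if not 0 < self.ellipse_confidence < 1:
            raise ValueError("ellipse_confidence must lie in (0, 1)")


def _valid_uv(seg: RoATrajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = seg.valid
    return seg.t[m], seg.ft[m], seg.fp[m]


def compute_reference(
    traj: RoATrajectory, region: AnalysisRegion, cfg: MetricConfig = MetricConfig()
) -> tuple[float, float]:
    """Initial-position reference for the AID family: mean centroid over
    the first ``baseline_s`` seconds of the analysis region."""
    base = traj.slice(region.start_s, region.start_s + cfg.baseline_s)
    _, u, v = _valid_uv(base)
    if u.size == 0:
        raise ValueError("no valid frames in the baseline window; AID reference undefined")
    return float(u.mean()), float(v.mean())


def aid(
    seg: RoATrajectory, reference: tuple[float, float] | None = None
) -> tuple[float, float, float]:
    """Mean activation-intensity distance from the reference point.

    Returns (resultant, FT component, FP component) in mm.  With no
    reference given, the segment mean is used (window_mean policy).
    """
    _, u, v = _valid_uv(seg)
    if u.size < 1:
        raise ValueError("empty segment")
    if reference is None:
        ru, rv = float(u.mean()), float(v.mean())
    else:
        ru, rv = reference
    x, y = u - ru, v - rv
    return (
        float(np.mean(np.hypot(x, y))),
        float(np.mean(np.abs(x))),
        float(np.mean(np.abs(y))),
    )


def aip(seg: RoATrajectory) -> tuple[float, float, float]:
    """Total excursion: path length of the trajectory within the segment.

    Missing frames are dropped before differencing.  Returns
    (resultant, FT, FP) in mm.
    """
    _, u, v = _valid_uv(seg)
    if u.size < 2:
        return (0.0, 0.0, 0.0)
    du, dv = np.diff(u), np.diff(v)
    return (
        float(np.sum(np.hypot(du, dv))),
        float(np.sum(np.abs(du))),
        float(np.sum(np.abs(dv))),
    )


def aiv(
    seg: RoATrajectory, duration_s: float | None = None
) -> tuple[float, float, float]:
    """Mean activation-intensity velocity: AIP / T, in mm/s.

    ``duration_s`` defaults to the time spanned by the valid frames.
    """
    t, u, _ = _valid_uv(seg)
    if duration_s is None:
        if t.size < 2:
            raise ValueError("cannot infer duration from fewer than 2 frames")
        duration_s = float(t[-1] - t[0])
    if duration_s <= 0:
        raise ValueError("segment duration must be positive")
    p, p_ft, p_fp = aip(seg)
    return p / duration_s, p_ft / duration_s, p_fp / duration_s


def spread(seg: RoATrajectory) -> tuple[float, float, float, float, float]:
    """(ais, std_ft, std_fp, avg_ft, avg_fp): per-segment position means,
    population standard deviations, and their resultant
    ais = sqrt(std_ft^2 + std_fp^2) — the RMS distance from the mean."""
    _, u, v = _valid_uv(seg)
    if u.size < 1:
        raise ValueError("empty segment")
    std_ft = float(u.std(ddof=0))
    std_fp = float(v.std(ddof=0))
    return (
        math.hypot(std_ft, std_fp),
        std_ft,
        std_fp,
        float(u.mean()),
        float(v.mean()),
    )


def aez(seg: RoATrajectory, confidence: float = 0.95) -> float:
    """Area of the confidence ellipse expected to contain ``confidence``
    of the trajectory points: 2 pi F(confidence; 2, N-2) sqrt(det S),
    with S the population covariance of the mean-centered samples.
    Degenerate (collinear) segments give area 0 with a warning.
    """
    _, u, v = _valid_uv(seg)
    n = u.size
    if n < 3:
        warnings.warn("fewer than 3 frames; confidence ellipse undefined, area 0",
                      stacklevel=2)
        return 0.0
    x, y = u - u.mean(), v - v.mean()
    s_u2 = float(np.mean(x * x))
    s_v2 = float(np.mean(y * y))
    s_uv = float(np.mean(x * y))
    det = s_u2 * s_v2 - s_uv**2
    if det <= 0:
        if det < -1e-12 * max(s_u2 * s_v2, 1e-300):
            warnings.warn("singular trajectory covariance; ellipse area 0", stacklevel=2)
        return 0.0
    f_crit = spstats.f.ppf(confidence, 2, n - 2)
    return float(2.0 * math.pi * f_crit * math.sqrt(det))


def acz(seg: RoATrajectory, z: float = 1.645) -> float:
    """Area of the confidence circle pi (mean RD + z std RD)^2 built on
    the mean-centered resultant distances RD."""
    _, u, v = _valid_uv(seg)
    if u.size < 1:
        raise ValueError("empty segment")
    rd = np.hypot(u - u.mean(), v - v.mean())
    radius = float(rd.mean() + z * rd.std(ddof=0))
    return math.pi * radius**2


def amz(seg: RoATrajectory, duration_s: float | None = None) -> float:
    """Sway-area analog: area swept about the segment mean per unit time,
    (1 / 2T) sum |x_n y_{n-1} - x_{n-1} y_n| over consecutive
    mean-centered samples.  Purely radial motion sweeps no area.
    """
    t, u, v = _valid_uv(seg)
    if u.size < 3:
        return 0.0
    if duration_s is None:
        duration_s = float(t[-1] - t[0])
    if duration_s <= 0:
        raise ValueError("segment duration must be positive")
    x, y = u - u.mean(), v - v.mean()
    cross = np.abs(x[1:] * y[:-1] - x[:-1] * y[1:])
    return float(cross.sum() / (2.0 * duration_s))


def displacement(traj: RoATrajectory, region: AnalysisRegion) -> float:
    """Euclidean distance between the mean centroid in T1 and in T3 (the
    classical between-segment shift of the activity center), in mm."""
    t1, t3 = region.segments[0], region.segments[2]
    means = []
    for seg in (t1, t3):
        _, u, v = _valid_uv(traj.slice(seg.start_s, seg.end_s))
        if u.size == 0:
            raise ValueError(f"segment {seg.label} has no valid frames")
        means.append((u.mean(), v.mean()))
    (u1, v1), (u3, v3) = means
    return float(math.hypot(u3 - u1, v3 - v1))


def _max_gap(t: np.ndarray) -> float:
    return float(np.max(np.diff(t))) if t.size >= 2 else math.inf


def segment_metrics(
    traj: RoATrajectory,
    env: EnvelopeSeries,
    spec: SpectralSeries,
    tq: TorqueTrace,
    region: AnalysisRegion,
    cfg: MetricConfig = MetricConfig(),
    good: np.ndarray | None = None,
) -> tuple[list[SegmentMetrics], dict[str, float]]:
    """All per-segment variables plus the per-variable maxima record.

    Computes, for T1/T2/T3: normalised torque mean and CoV, spatial
    envelope mean, grid AIF, and the full spatial suite on the centroid
    trajectory.  The maxima record (element-wise max over the three
    segments) feeds the endurance-time regression.  Constituent failures
    propagate as NaN.
    """
    torque_stats = torque_segment_stats(tq, region)
    env_means = envelope_segment_mean(env, region, good=good)
    aif_means = aif_segment_mean(spec, region, good=good)

    if cfg.reference_policy == "baseline":
        reference = compute_reference(traj, region, cfg)
    else:
        reference = None

    rows: list[SegmentMetrics] = []
    for seg in region:
        m = SegmentMetrics(label=seg.label)
        m.torque_mean, m.torque_cov = torque_stats[seg.label]
        m.envelope_mean = env_means[seg.label]
        m.aif = aif_means[seg.label]
        sub = traj.slice(seg.start_s, seg.end_s)
        t_valid = sub.t[sub.valid]
        if t_valid.size >= 2:
            try:
                m.aid, m.aid_ft, m.aid_fp = aid(sub, reference)
            except ValueError:
                pass
            m.ais, m.std_ft, m.std_fp, m.avg_ft, m.avg_fp = spread(sub)
            m.aez = aez(sub, cfg.ellipse_confidence)
            m.acz = acz(sub, cfg.circle_z)
            if _max_gap(t_valid) <= cfg.max_gap_s:
                m.aip, m.aip_ft, m.aip_fp = aip(sub)
                m.aiv, m.aiv_ft, m.aiv_fp = (
                    float(x / seg.duration_s) for x in (m.aip, m.aip_ft, m.aip_fp)
                )
                m.amz = amz(sub, duration_s=seg.duration_s)
            else:
                warnings.warn(
                    f"segment {seg.label}: frame gap exceeds {cfg.max_gap_s:g} s; "
                    "path metrics undefined",
                    stacklevel=2,
                )
        rows.append(m)

    maxima: dict[str, float] = {}
    for name in rows[0].as_dict():
        vals = np.array([getattr(r, name) for r in rows], dtype=float)
        maxima[name] = float(np.nanmax(vals)) if np.isfinite(vals).any() else math.nan
    return rows, maxima
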