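"""Shared data model for spatiotemporal HD-sEMG analysis.

High-density surface EMG is recorded with a rectangular electrode grid
placed over one muscle.  Everything downstream — amplitude topographies,
the Region of Activation (RoA) trajectory and the sway-style spatial
metrics — speaks in the grid's physical coordinate frame:

* FT (fiber-transverse) = x = columns, in mm, origin at column 0;
* FP (fiber-parallel)   = y = rows,    in mm, origin at row 0.

Row 0 is taken as the cranial end and column 0 as the medial edge; the
anatomical orientation of a real montage is a documented convention, not
something the arithmetic depends on.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

Position = tuple[int, int]

#: Upper edge of the surface-EMG analysis band in Hz; recordings must be
#: sampled above twice this frequency.
EMG_BAND_UPPER_HZ = 450.0


def _default_missing() -> frozenset[Position]:
    # Two 13x5 grids fused into 26x5; each constituent grid lacks one
    # corner electrode (used by the hardware to mark orientation).
    return frozenset({(0, 4), (13, 4)})


@dataclass(frozen=True)
class GridLayout:
    """Electrode grid geometry and channel masks.

    Defaults describe the fused 26x5 montage (two 13x5 grids stacked
    along the fiber direction, 8 mm inter-electrode distance, one corner
    electrode absent per constituent grid → 128 physical channels,
    spanning 200 x 32 mm).
    """

    n_rows: int = 26
    n_cols: int = 5
    ied_fp: float = 8.0
    ied_ft: float = 8.0
    missing: frozenset[Position] = field(default_factory=_default_missing)
    bad: frozenset[Position] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.ied_fp <= 0 or self.ied_ft <= 0:
            raise ValueError("inter-electrode distances must be positive")
        object.__setattr__(self, "missing", frozenset(map(tuple, self.missing)))
        object.__setattr__(self, "bad", frozenset(map(tuple, self.bad)))
        for name in ("missing", "bad"):
            for (r, c) in getattr(self, name):
                if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                    raise ValueError(f"{name} position {(r, c)} off the lattice")

    @property
    def n_channels(self) -> int:
        """Number of physical electrodes (non-missing lattice positions)."""
        return self.n_rows * self.n_cols - len(self.missing)

    @property
    def span_ft(self) -> float:
        """Grid extent in the fiber-transverse direction, mm."""
        return (self.n_cols - 1) * self.ied_ft

    @property
    def span_fp(self) -> float:
        """Grid extent in the fiber-parallel direction, mm."""
        return (self.n_rows - 1) * self.ied_fp

    def positions(self) -> list[Position]:
        """Row-major list of physical electrode positions."""
        return [
            (r, c)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
            if (r, c) not in self.missing
        ]

    def with_bad(self, bad: Sequence[Position]) -> "GridLayout":
        return dataclasses.replace(self, bad=frozenset(map(tuple, bad)))


def coords_of(layout: GridLayout, row: int, col: int) -> tuple[float, float]:
    """Physical (ft, fp) coordinates in mm of a lattice position.

    ``ft = col * ied_ft`` and ``fp = row * ied_fp``; raises for indices
    off the lattice (missing electrodes still have coordinates).
    """
    if not (0 <= row < layout.n_rows and 0 <= col < layout.n_cols):
        raise IndexError(f"position {(row, col)} off the {layout.n_rows}x{layout.n_cols} lattice")
    return col * layout.ied_ft, row * layout.ied_fp


def grid_coordinates(layout: GridLayout, channel_map: Sequence[Position]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (ft, fp) coordinate arrays for a channel map."""
    rows = np.array([p[0] for p in channel_map], dtype=float)
    cols = np.array([p[1] for p in channel_map], dtype=float)
    return cols * layout.ied_ft, rows * layout.ied_fp


@dataclass
class EMGRecording:
    """Monopolar multichannel sEMG: a channels x samples matrix in mV.

    ``channel_map[i]`` gives the (row, col) lattice position of channel
    ``i``; by default channels are laid out row-major over the physical
    (non-missing) positions.
    """

    signals: np.ndarray
    fs: float
    layout: GridLayout = field(default_factory=GridLayout)
    channel_map: tuple[Position, ...] = ()

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D channels x samples matrix")
        if not self.channel_map:
            self.channel_map = tuple(self.layout.positions())
        else:
            self.channel_map = tuple(map(tuple, self.channel_map))

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def index_of(self, row: int, col: int) -> int:
        return self.channel_map.index((row, col))

    def good_channel_mask(self, bad: set[Position] | frozenset[Position] | None = None) -> np.ndarray:
        """Boolean mask over channels excluding layout.bad (plus extras)."""
        excluded = set(self.layout.bad)
        if bad:
            excluded |= set(map(tuple, bad))
        return np.array([p not in excluded for p in self.channel_map])


def validate_recording(rec: EMGRecording) -> list[str]:
    """Check recording invariants; returns one finding per violation.

    An empty list means the recording is well formed.  Findings are
    reported rather than raised so callers can aggregate them.
    """
    findings: list[str] = []
    if rec.signals.ndim != 2:
        findings.append("signals must be 2-D (channels x samples)")
        return findings
    if rec.fs <= 2 * EMG_BAND_UPPER_HZ:
        findings.append(
            f"fs={rec.fs:g} Hz below 2x{EMG_BAND_UPPER_HZ:g} Hz; bandpass upper edge exceeds Nyquist"
        )
    if rec.n_channels != rec.layout.n_channels:
        findings.append(
            f"channel count mismatch: {rec.n_channels} signals for "
            f"{rec.layout.n_channels} physical electrodes"
        )
    if len(rec.channel_map) != rec.n_channels:
        findings.append("channel_map length does not match channel count")
    else:
        seen = set(rec.channel_map)
        if len(seen) != len(rec.channel_map):
            findings.append("channel_map contains duplicate positions")
        off = [p for p in seen if p in rec.layout.missing]
        if off:
            findings.append(f"channel_map assigns signals to missing positions {sorted(off)}")
        for (r, c) in seen:
            if not (0 <= r < rec.layout.n_rows and 0 <= c < rec.layout.n_cols):
                findings.append(f"channel_map position {(r, c)} off the lattice")
                break
    if not np.all(np.isfinite(rec.signals)):
        findings.append("signals contain non-finite values")
    return findings


@dataclass
class TorqueTrace:
    """Single-channel torque record with its normalisation constants.

    ``mvt`` is the subject's maximum voluntary torque in N·m; the
    fatiguing contraction targets ``target_fraction`` of it (0.60 by
    default).
    """

    torque: np.ndarray
    fs: float
    mvt: float
    target_fraction: float = 0.60

    def __post_init__(self) -> None:
        self.torque = np.asarray(self.torque, dtype=float).ravel()
        if self.fs <= 20:
            raise ValueError("torque sampling rate must exceed 20 Hz")
        if self.mvt <= 0:
            raise ValueError("MVT must be positive")
        if not 0 < self.target_fraction < 1:
            raise ValueError("target_fraction must lie in (0, 1)")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.torque.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.torque.size / self.fs


@dataclass(frozen=True)
class Segment:
    label: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class AnalysisRegion:
    """The analysed portion of the contraction and its three segments.

    The region lies strictly between the two quasi-zero torque windows;
    T1 starts at the region start, T3 ends at the region end and T2 is
    centered at the region midpoint.  Each segment is
    ``segment_length_s`` long (10 s by default); for short regions the
    segments may overlap.
    """

    start_s: float
    end_s: float
    segments: tuple[Segment, Segment, Segment]
    quasi_zero: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("region start must precede region end")
        for seg in self.segments:
            if seg.start_s < self.start_s - 1e-9 or seg.end_s > self.end_s + 1e-9:
                raise ValueError(f"segment {seg.label} outside the analysis region")

    @classmethod
    def from_bounds(
        cls,
        start_s: float,
        end_s: float,
        segment_length_s: float = 10.0,
        quasi_zero: tuple[tuple[float, float], tuple[float, float]] | None = None,
    ) -> "AnalysisRegion":
        length = end_s - start_s
        if length < segment_length_s:
            raise ValueError(
                f"analysis region ({length:.2f} s) shorter than one segment "
                f"({segment_length_s:.2f} s)"
            )
        mid = 0.5 * (start_s + end_s)
        segments = (
            Segment("T1", start_s, start_s + segment_length_s),
            Segment("T2", mid - segment_length_s / 2, mid + segment_length_s / 2),
            Segment("T3", end_s - segment_length_s, end_s),
        )
        return cls(start_s, end_s, segments, quasi_zero)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)


@dataclass
class RoATrajectory:
    """Time series of activation-centroid coordinates at the map rate.

    ``ft`` / ``fp`` are in mm; frames where the centroid could not be
    computed hold NaN and are excluded downstream.
    """

    t: np.ndarray
    ft: np.ndarray
    fp: np.ndarray
    kind: str = "RoA"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float).ravel()
        self.ft = np.asarray(self.ft, dtype=float).ravel()
        self.fp = np.asarray(self.fp, dtype=float).ravel()
        if not (self.t.size == self.ft.size == self.fp.size):
            raise ValueError("t, ft, fp must have equal length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trajectory timebase must be strictly increasing")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.ft) & np.isfinite(self.fp)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def slice(self, start_s: float, end_s: float) -> "RoATrajectory":
        # half-open [start, end): adjacent segments never share a frame
        sel = (self.t >= start_s - 1e-9) & (self.t < end_s - 1e-9)
        return RoATrajectory(self.t[sel], self.ft[sel], self.fp[sel], self.kind)


#: Table-1 style variable names, in reporting order.
METRIC_FIELDS = (
    "torque_mean",
    "torque_cov",
    "envelope_mean",
    "aif",
    "aid",
    "aid_fp",
    "aid_ft",
    "aip",
    "aip_fp",
    "aip_ft",
    "aiv",
    "aiv_fp",
    "aiv_ft",
    "aez",
    "amz",
    "acz",
    "ais",
    "std_ft",
    "std_fp",
    "avg_ft",
    "avg_fp",
)


@dataclass
class SegmentMetrics:
    """All per-segment variables: torque, amplitude, spectral, spatial.

    Units: torque_mean / torque_cov dimensionless (normalised to MVT),
    envelope_mean mV, aif Hz, distances mm, velocities mm/s, areas mm²
    (amz mm²/s), spreads mm.
    """

    label: str
    torque_mean: float = math.nan
    torque_cov: float = math.nan
    envelope_mean: float = math.nan
    aif: float = math.nan
    aid: float = math.nan
    aid_fp: float = math.nan
    aid_ft: float = math.nan
    aip: float = math.nan
    aip_fp: float = math.nan
    aip_ft: float = math.nan
    aiv: float = math.nan
    aiv_fp: float = math.nan
    aiv_ft: float = math.nan
    aez: float = math.nan
    amz: float = math.nan
    acz: float = math.nan
    ais: float = math.nan
    std_ft: float = math.nan
    std_fp: float = math.nan
    avg_ft: float = math.nan
    avg_fp: float = math.nan

    def as_dict(self) -> dict[str, float]:
        d = dataclasses.asdict(self)
        d.pop("label")
        return d

    def check_invariants(self, rtol: float = 1e-9, atol: float = 1e-9) -> list[str]:
        problems: list[str] = []
        for name in ("aid", "aid_fp", "aid_ft", "aip", "aip_fp", "aip_ft",
                     "aiv", "aiv_fp", "aiv_ft", "aez", "amz", "acz",
                     "ais", "std_ft", "std_fp"):
            v = getattr(self, name)
            if np.isfinite(v) and v < -atol:
                problems.append(f"{name} negative ({v:g})")
        if np.isfinite(self.ais) and np.isfinite(self.std_ft) and np.isfinite(self.std_fp):
            if not math.isclose(self.ais**2, self.std_ft**2 + self.std_fp**2,
                                rel_tol=rtol, abs_tol=atol):
                problems.append("ais^2 != std_ft^2 + std_fp^2")
        return problems
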