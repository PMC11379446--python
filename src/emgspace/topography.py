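"""Amplitude topographies and activation-centroid trajectories.

Each envelope frame becomes a rows x cols map of muscle activity; the
Region of Activation (RoA) is the amplitude-weighted centroid of the
cells at or above 70 % of the map's maximum, and the Centre of Gravity
(CoG) is the same centroid taken over every defined cell (threshold 0).
Bad and missing electrodes are *undefined* (NaN), never zero — they
carry no weight and no coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_types import GridLayout, Position, RoATrajectory
from .features import EnvelopeSeries


@dataclass
class ActivationMap:
    """One topographical frame: rows x cols amplitudes (mV), NaN where
    no electrode or a bad electrode sits."""

    amplitude: np.ndarray
    t: float

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.amplitude)


def maps_from_envelope(
    env: EnvelopeSeries,
    layout: GridLayout,
    channel_map: Sequence[Position],
    bad: set[Position] | frozenset[Position] | None = None,
) -> list[ActivationMap]:
    """One map per envelope frame; bad/missing cells are left undefined."""
    excluded = set(layout.bad) | (set(map(tuple, bad)) if bad else set())
    frames = []
    base = np.full((layout.n_rows, layout.n_cols), np.nan)
    rows = np.array([p[0] for p in channel_map])
    cols = np.array([p[1] for p in channel_map])
    keep = np.array([p not in excluded for p in channel_map])
    for k in range(env.n_frames):
        grid = base.copy()
        grid[rows[keep], cols[keep]] = env.values[keep, k]
        frames.append(ActivationMap(amplitude=grid, t=float(env.t[k])))
    return frames


def roa(
    amap: ActivationMap, layout: GridLayout, threshold_fraction: float = 0.7
) -> tuple[float, float]:
    """Weighted centroid of cells >= threshold_fraction x local maximum.

    Returns (ft, fp) in mm.  Ties at the threshold are included.  For an
    all-zero (but defined) map the active cells carry no weight and the
    unweighted centroid of the active set is returned, which for
    threshold 0 is the geometric center of the defined cells.
    """
    amp = amap.amplitude
    defined = np.isfinite(amp)
    if not defined.any():
        raise ValueError("map has no defined cells")
    local_max = np.nanmax(amp)
    active = defined & (amp >= threshold_fraction * local_max)
    rows, cols = np.nonzero(active)
    w = amp[active]
    total = w.sum()
    ft_coords = cols * layout.ied_ft
    fp_coords = rows * layout.ied_fp
    if total > 0:
        return float(w @ ft_coords / total), float(w @ fp_coords / total)
    return float(ft_coords.mean()), float(fp_coords.mean())


def cog(amap: ActivationMap, layout: GridLayout) -> tuple[float, float]:
    """Weighted centroid of the whole defined grid (threshold-free RoA)."""
    return roa(amap, layout, threshold_fraction=0.0)


def roa_trajectory(
    maps: Sequence[ActivationMap],
    layout: GridLayout,
    threshold_fraction: float = 0.7,
    kind: str = "RoA",
) -> RoATrajectory:
    """Per-frame centroid; frames that cannot be computed become NaN."""
    if len(maps) == 0:
        raise ValueError("no maps provided")
    t = np.array([m.t for m in maps])
    ft = np.full(len(maps), np.nan)
    fp = np.full(len(maps), np.nan)
    for i, m in enumerate(maps):
        try:
            ft[i], fp[i] = roa(m, layout, threshold_fraction)
        except ValueError:
            continue
    return RoATrajectory(t=t, ft=ft, fp=fp, kind=kind)


def interpolate_bad(amap: ActivationMap) -> ActivationMap:
    """Fill undefined cells with the mean of their defined 4-neighbours.

    Intended for visualisation only — centroid extraction always runs on
    the raw map.  Cells with no defined neighbour stay undefined.
    """
    amp = amap.amplitude
    out = amp.copy()
    n_rows, n_cols = amp.shape
    holes = np.argwhere(~np.isfinite(amp))
    for r, c in holes:
        vals = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and np.isfinite(amp[rr, cc]):
                vals.append(amp[rr, cc])
        if vals:
            out[r, c] = float(np.mean(vals))
    return ActivationMap(amplitude=out, t=amap.t)
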