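"""Shared fixtures: small grids and fast simulated subjects.

Simulations used throughout the suite run at 1024 Hz on reduced grids
and shortened holds — large enough for every statistical check, small
enough that the whole suite stays quick.
"""

from __future__ import annotations

import numpy as np
import pytest

from emgspace import (
    EMGRecording,
    GridLayout,
    RoATrajectory,
    SimulationConfig,
    filter_emg,
    filter_torque,
    maps_from_envelope,
    rms_envelope,
    roa_trajectory,
    segment_contraction,
)
from emgspace.preprocess import FilterSpec
from emgspace.simulate import drift_path


@pytest.fixture(scope="session")
def default_layout() -> GridLayout:
    return GridLayout()


@pytest.fixture(scope="session")
def small_layout() -> GridLayout:
    """A 16x5 grid (one missing corner): same geometry, fewer channels."""
    return GridLayout(n_rows=16, n_cols=5, missing=frozenset({(0, 4)}))


def fast_config(layout: GridLayout, seed: int = 0, **overrides) -> SimulationConfig:
    """Scaled-down study conditions for quick simulation."""
    defaults = dict(
        layout=layout,
        fs=1024.0,
        duration_s=46.0,
        failure_time_s=42.0,
        kernel_sigma_ft=10.0,
        kernel_sigma_fp=25.0,
        noise_floor=0.002,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def track_centroid(rec: EMGRecording, tq, threshold_fraction: float = 0.7):
    """Lean conditioning + tracking chain (no AIF, no bad-channel scan)."""
    spec = FilterSpec()
    tq_f = filter_torque(tq, spec)
    region = segment_contraction(tq_f)
    rec_f = filter_emg(rec, spec)
    env = rms_envelope(rec_f)
    maps = maps_from_envelope(env, rec.layout, rec.channel_map)
    traj = roa_trajectory(maps, rec.layout, threshold_fraction)
    return region, traj, env


@pytest.fixture(scope="session")
def drifting_subject(small_layout):
    """One simulated subject with a known 20 mm fiber-parallel drift."""
    cfg = fast_config(
        small_layout,
        seed=11,
        center_path=drift_path(small_layout, 46.0, drift_fp=20.0,
                               start_s=6.0, end_s=40.0),
    )
    from emgspace import simulate_subject

    rec, tq, truth = simulate_subject(cfg)
    return cfg, rec, tq, truth


def random_trajectory(rng: np.random.Generator, n: int = 50,
                      frame_rate: float = 10.0) -> RoATrajectory:
    t = np.arange(n) / frame_rate
    return RoATrajectory(
        t=t,
        ft=rng.normal(16.0, 2.0, n),
        fp=rng.normal(100.0, 5.0, n),
    )
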