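"""The sway-derived spatial metric suite: oracles and invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgspace import (
    AnalysisRegion,
    RoATrajectory,
    acz,
    aez,
    aid,
    aip,
    aiv,
    amz,
    displacement,
    spread,
)
from emgspace.spatial_metrics import MetricConfig, compute_reference

from conftest import random_trajectory


def _traj(u, v, dt=0.1):
    u = np.asarray(u, dtype=float)
    return RoATrajectory(t=np.arange(u.size) * dt, ft=u, fp=np.asarray(v, float))


# ---------------------------------------------------------------- oracles

def oracle_aid(u, v, ru, rv):
    d = [math.hypot(x - ru, y - rv) for x, y in zip(u, v)]
    return (sum(d) / len(d),
            sum(abs(x - ru) for x in u) / len(u),
            sum(abs(y - rv) for y in v) / len(v))


def oracle_aip(u, v):
    tot = ft = fp = 0.0
    for i in range(1, len(u)):
        du, dv = u[i] - u[i - 1], v[i] - v[i - 1]
        tot += math.hypot(du, dv)
        ft += abs(du)
        fp += abs(dv)
    return tot, ft, fp


def oracle_amz(u, v, duration):
    mu, mv = sum(u) / len(u), sum(v) / len(v)
    x = [a - mu for a in u]
    y = [b - mv for b in v]
    area = 0.0
    for i in range(1, len(x)):
        area += abs(x[i] * y[i - 1] - x[i - 1] * y[i])
    return area / (2 * duration)


def oracle_spread(u, v):
    mu, mv = sum(u) / len(u), sum(v) / len(v)
    su = math.sqrt(sum((a - mu) ** 2 for a in u) / len(u))
    sv = math.sqrt(sum((b - mv) ** 2 for b in v) / len(v))
    return math.hypot(su, sv), su, sv, mu, mv


# ---------------------------------------------------------------- examples

class TestAID:
    def test_constant_at_reference(self):
        tr = _traj([2.0] * 5, [3.0] * 5)
        assert aid(tr, reference=(2.0, 3.0)) == pytest.approx((0, 0, 0))

    def test_three_four_five(self):
        tr = _traj([3.0, 3.0], [4.0, 4.0])
        assert aid(tr, reference=(0.0, 0.0)) == pytest.approx((5.0, 3.0, 4.0))

    def test_uniform_circle_converges_to_radius(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 2 * np.pi, 20000)
        tr = _traj(5.0 * np.cos(theta), 5.0 * np.sin(theta))
        a, _, _ = aid(tr, reference=(0.0, 0.0))
        assert a == pytest.approx(5.0, rel=0.01)

    def test_default_reference_is_segment_mean(self):
        tr = _traj([0.0, 2.0], [0.0, 0.0])
        assert aid(tr) == pytest.approx((1.0, 1.0, 0.0))


class TestAIP:
    def test_constant_trajectory(self):
        assert aip(_traj([1.0] * 10, [2.0] * 10)) == pytest.approx((0, 0, 0))

    def test_single_step(self):
        assert aip(_traj([0.0, 3.0], [0.0, 4.0])) == pytest.approx((5.0, 3.0, 4.0))

    def test_unit_square(self):
        u = [0.0, 1.0, 1.0, 0.0, 0.0]
        v = [0.0, 0.0, 1.0, 1.0, 0.0]
        assert aip(_traj(u, v)) == pytest.approx((4.0, 2.0, 2.0))

    def test_missing_frames_dropped_before_differencing(self):
        u = np.array([0.0, np.nan, 3.0])
        v = np.array([0.0, np.nan, 4.0])
        assert aip(_traj(u, v)) == pytest.approx((5.0, 3.0, 4.0))


class TestAIV:
    def test_definition(self):
        tr = _traj([0.0, 50.0], [0.0, 0.0], dt=10.0)
        assert aiv(tr, duration_s=10.0) == pytest.approx((5.0, 5.0, 0.0))

    def test_proportional_to_aip(self):
        rng = np.random.default_rng(1)
        tr = random_trajectory(rng, 80)
        p = aip(tr)
        V = aiv(tr, duration_s=7.9)
        assert all(vi * 7.9 == pytest.approx(pi, rel=1e-12) for vi, pi in zip(V, p))

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            aiv(_traj([0.0, 1.0], [0.0, 1.0]), duration_s=0.0)


class TestSpread:
    def test_constant(self):
        ais_, sft, sfp, aft, afp = spread(_traj([3.0] * 4, [7.0] * 4))
        assert (ais_, sft, sfp) == (0.0, 0.0, 0.0)
        assert (aft, afp) == (3.0, 7.0)

    def test_two_level(self):
        ais_, sft, sfp, _, _ = spread(_traj([0.0, 2.0, 0.0, 2.0], [5.0] * 4))
        assert sft == pytest.approx(1.0)
        assert sfp == 0.0
        assert ais_ == pytest.approx(1.0)

    def test_isotropic_gaussian(self):
        rng = np.random.default_rng(2)
        tr = _traj(rng.normal(0, 2.0, 40000), rng.normal(0, 2.0, 40000))
        ais_, *_ = spread(tr)
        assert ais_ == pytest.approx(2.0 * math.sqrt(2.0), rel=0.02)


class TestAEZ:
    def test_collinear_degenerate(self):
        u = np.linspace(0, 10, 50)
        assert aez(_traj(u, 2 * u + 1)) == 0.0

    def test_large_n_isotropic_gaussian(self):
        rng = np.random.default_rng(3)
        n = 50000
        tr = _traj(rng.normal(0, 1.0, n), rng.normal(0, 1.0, n))
        # F(0.95; 2, inf) -> 2.9957: area -> 2 pi * 3.0 * sigma^2
        assert aez(tr) == pytest.approx(2 * math.pi * 2.9957, rel=0.03)

    def test_fewer_than_three_frames_warns(self):
        with pytest.warns(UserWarning):
            assert aez(_traj([0.0, 1.0], [0.0, 1.0])) == 0.0


class TestACZ:
    def test_constant_trajectory(self):
        assert acz(_traj([1.0] * 5, [1.0] * 5)) == 0.0

    def test_ring_gives_exact_circle_area(self):
        theta = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        tr = _traj(3.0 * np.cos(theta), 3.0 * np.sin(theta))
        assert acz(tr) == pytest.approx(math.pi * 9.0, rel=1e-9)


class TestAMZ:
    def test_constant(self):
        assert amz(_traj([1.0] * 5, [1.0] * 5)) == 0.0

    def test_radial_motion_sweeps_nothing(self):
        u = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        assert amz(_traj(u, 2.0 * u)) == pytest.approx(0.0, abs=1e-12)

    def test_circle_swept_area(self):
        n, R, T = 10000, 4.0, 10.0
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        tr = RoATrajectory(t=np.linspace(0, T, n),
                           ft=R * np.cos(theta), fp=R * np.sin(theta))
        assert amz(tr, duration_s=T) == pytest.approx(math.pi * R**2 / T, rel=0.005)

    def test_matches_shoelace_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            tr = random_trajectory(rng, 50)
            want = oracle_amz(tr.ft.tolist(), tr.fp.tolist(), 4.9)
            assert amz(tr, duration_s=4.9) == pytest.approx(want, abs=1e-9)


class TestDisplacement:
    def _region(self):
        return AnalysisRegion.from_bounds(0.0, 30.0, 10.0)

    def test_identical_segments(self):
        tr = _traj([1.0] * 300, [2.0] * 300)
        assert displacement(tr, self._region()) == pytest.approx(0.0)

    def test_three_four_five(self):
        u = np.concatenate([np.zeros(100), np.zeros(100), np.full(100, 3.0)])
        v = np.concatenate([np.zeros(100), np.zeros(100), np.full(100, 4.0)])
        assert displacement(_traj(u, v), self._region()) == pytest.approx(5.0)

    def test_empty_segment_is_an_error(self):
        tr = _traj(np.full(300, np.nan), np.full(300, np.nan))
        with pytest.raises(ValueError):
            displacement(tr, self._region())


class TestReference:
    def test_baseline_reference_is_first_second_mean(self):
        region = AnalysisRegion.from_bounds(0.0, 30.0, 10.0)
        u = np.concatenate([np.full(10, 4.0), np.zeros(290)])
        tr = _traj(u, u)
        assert compute_reference(tr, region) == pytest.approx((4.0, 4.0))

    def test_empty_baseline_is_an_error(self):
        region = AnalysisRegion.from_bounds(0.0, 30.0, 10.0)
        u = np.concatenate([np.full(10, np.nan), np.zeros(290)])
        with pytest.raises(ValueError):
            compute_reference(_traj(u, u), region)


# ------------------------------------------------------- oracle sweeps

class TestAgainstBruteForce:
    def test_random_trajectories(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            tr = random_trajectory(rng, 50)
            u, v = tr.ft.tolist(), tr.fp.tolist()
            assert aid(tr) == pytest.approx(oracle_aid(u, v, np.mean(u), np.mean(v)),
                                            abs=1e-9)
            assert aip(tr) == pytest.approx(oracle_aip(u, v), abs=1e-9)
            assert spread(tr) == pytest.approx(oracle_spread(u, v), abs=1e-9)


# ---------------------------------------------------------- invariances

def _rotate(tr, angle):
    c, s = math.cos(angle), math.sin(angle)
    return RoATrajectory(t=tr.t, ft=c * tr.ft - s * tr.fp, fp=s * tr.ft + c * tr.fp)


class TestInvariances:
    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        tr = random_trajectory(rng, 60)
        shifted = RoATrajectory(t=tr.t, ft=tr.ft + 11.0, fp=tr.fp - 7.0)
        ref = (float(tr.ft.mean()), float(tr.fp.mean()))
        ref_s = (ref[0] + 11.0, ref[1] - 7.0)
        assert aid(shifted, ref_s) == pytest.approx(aid(tr, ref), abs=1e-9)
        assert aip(shifted) == pytest.approx(aip(tr), abs=1e-9)
        assert spread(shifted)[:3] == pytest.approx(spread(tr)[:3], abs=1e-9)
        assert aez(shifted) == pytest.approx(aez(tr), abs=1e-9)
        assert acz(shifted) == pytest.approx(acz(tr), abs=1e-9)
        assert amz(shifted) == pytest.approx(amz(tr), abs=1e-9)

    def test_rotation_invariance_of_resultant_metrics(self):
        rng = np.random.default_rng(7)
        tr = random_trajectory(rng, 60)
        rot = _rotate(tr, 0.73)
        ref = (float(tr.ft.mean()), float(tr.fp.mean()))
        ref_r = (float(rot.ft.mean()), float(rot.fp.mean()))
        assert aid(rot, ref_r)[0] == pytest.approx(aid(tr, ref)[0], abs=1e-9)
        assert aip(rot)[0] == pytest.approx(aip(tr)[0], abs=1e-9)
        assert spread(rot)[0] == pytest.approx(spread(tr)[0], abs=1e-9)
        assert aez(rot) == pytest.approx(aez(tr), abs=1e-9)
        assert acz(rot) == pytest.approx(acz(tr), abs=1e-9)
        assert amz(rot) == pytest.approx(amz(tr), abs=1e-9)

    def test_spatial_scaling_laws(self):
        rng = np.random.default_rng(8)
        tr = random_trajectory(rng, 60)
        s = 2.5
        scaled = RoATrajectory(t=tr.t, ft=s * tr.ft, fp=s * tr.fp)
        assert aip(scaled)[0] == pytest.approx(s * aip(tr)[0], rel=1e-12)
        assert aid(scaled)[0] == pytest.approx(s * aid(tr)[0], rel=1e-12)
        assert aez(scaled) == pytest.approx(s**2 * aez(tr), rel=1e-9)
        assert acz(scaled) == pytest.approx(s**2 * acz(tr), rel=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
                    min_size=3, max_size=40))
    def test_spread_identity_and_nonnegativity(self, points):
        u = [p[0] for p in points]
        v = [p[1] for p in points]
        tr = _traj(u, v)
        ais_, sft, sfp, _, _ = spread(tr)
        assert ais_ == pytest.approx(math.hypot(sft, sfp), abs=1e-9)
        assert ais_ >= 0 and sft >= 0 and sfp >= 0
        assert aip(tr)[0] >= 0
        assert aez(tr) >= 0
        assert acz(tr) >= 0
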