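"""Behavioral indices: worked examples, identities and bound properties."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from swimmetrics.arena import assign_zones, make_equal_area_well, make_peripheral_band
from swimmetrics.errors import DataError
from swimmetrics.io import bin_activity
from swimmetrics.metrics import (
    activity_change,
    center_distance_ratio,
    habituation_index,
    ptz_response,
    spi,
    thigmotaxis_adult,
    thigmotaxis_larval,
    velocity,
)
from swimmetrics.protocol import StimulusWindowPair, ptz_challenge

from conftest import make_traj


def _bins(values, dt=1.0, t0=0.0, sid="s1"):
    import pandas as pd

    values = np.asarray(values, float)
    return pd.DataFrame(
        {"subject_id": sid, "t_start": t0 + dt * np.arange(len(values)),
         "dt": dt, "distance": values}
    )


class TestCenterRatio:
    def test_trajectory_entirely_in_center(self):
        well = make_equal_area_well(10.0)
        t = np.arange(0, 5, 0.04)
        za = assign_zones(make_traj(t, 2 * np.cos(t), 2 * np.sin(t)), well)
        assert center_distance_ratio(za) == pytest.approx(1.0)
        assert thigmotaxis_larval(za) == pytest.approx(0.0)

    def test_zero_distance_is_undefined_not_zero(self):
        well = make_equal_area_well(10.0)
        za = assign_zones(make_traj([0, 1, 2], [1, 1, 1], [0, 0, 0]), well)
        assert math.isnan(center_distance_ratio(za))

    def test_adult_partition_identity(self, random_walk_traj):
        tank = make_peripheral_band(60.0, 60.0)
        za = assign_zones(random_walk_traj, tank)
        center_frac = za.distance_in("center") / za.total_distance()
        assert thigmotaxis_adult(za) + center_frac == pytest.approx(1.0)

    def test_wall_hugging_is_full_thigmotaxis(self):
        tank = make_peripheral_band(300.0, 300.0)
        t = np.arange(0, 10, 0.04)
        # back and forth along one wall, well inside the peripheral band
        za = assign_zones(make_traj(t, 140 * np.sin(t), np.full_like(t, -140.0)), tank)
        assert thigmotaxis_adult(za) == pytest.approx(1.0)


class TestSpi:
    @pytest.mark.parametrize(
        "a,b,expected", [(300.0, 300.0, 0.0), (600.0, 0.0, 1.0), (400.0, 200.0, 1 / 3)]
    )
    def test_worked_examples(self, a, b, expected):
        assert spi(a, b) == pytest.approx(expected)

    def test_undefined_when_both_zero(self):
        assert math.isnan(spi(0.0, 0.0))

    @given(
        a=st.floats(0.001, 1e6),
        b=st.floats(0.001, 1e6),
        c=st.floats(0.01, 100.0),
    )
    def test_antisymmetry_scale_invariance_and_bounds(self, a, b, c):
        v = spi(a, b)
        assert -1.0 <= v <= 1.0
        assert spi(b, a) == pytest.approx(-v, abs=1e-12)
        assert spi(c * a, c * b) == pytest.approx(v, abs=1e-9)


class TestVelocity:
    def test_constant_speed(self):
        t = np.arange(0, 10, 0.04)
        traj = make_traj(t, 10.0 * t, np.zeros_like(t))
        assert velocity(traj=traj) == pytest.approx(10.0, rel=1e-9)

    def test_stationary(self):
        t = np.arange(0, 10, 0.04)
        assert velocity(traj=make_traj(t, np.ones_like(t), np.ones_like(t))) == 0.0

    def test_equals_mean_of_one_second_bins(self, random_walk_traj):
        window = (0.0, 59.0)
        bins = bin_activity(random_walk_traj, 1.0)
        v_traj = velocity(traj=random_walk_traj, window=window)
        v_bins = velocity(bins=bins, window=window)
        assert v_traj == pytest.approx(v_bins, rel=1e-9)
        assert v_bins == pytest.approx(
            bins[bins["t_start"] < 59.0]["distance"].mean(), rel=1e-9
        )


class TestActivityChange:
    def _wp(self):
        return StimulusWindowPair(onset=60.0, pre_start=0.0, post_stop=75.0)

    def test_worked_example(self):
        series = _bins([12.0] * 60 + [30.0] * 15)
        assert activity_change(series, self._wp()) == pytest.approx(18.0)

    def test_identical_windows_give_zero(self):
        series = _bins([7.0] * 75)
        assert activity_change(series, self._wp()) == 0.0

    def test_uncovered_window_is_error(self):
        series = _bins([1.0] * 40)
        with pytest.raises(DataError, match="does not cover"):
            activity_change(series, self._wp())

    @given(c=st.floats(0.01, 50.0))
    def test_linearity(self, c):
        rng = np.random.default_rng(7)
        vals = rng.random(75) * 5
        base = activity_change(_bins(vals), self._wp())
        scaled = activity_change(_bins(c * vals), self._wp())
        assert scaled == pytest.approx(c * base, rel=1e-9)


class TestHabituation:
    def test_worked_example(self):
        assert habituation_index([30.0, 20.0, 10.0]) == pytest.approx(2 / 3)

    def test_constant_responses(self):
        assert habituation_index([5.0, 5.0, 5.0]) == 0.0

    def test_non_positive_first_response_undefined(self):
        assert math.isnan(habituation_index([0.0, 1.0]))

    def test_needs_two_responses(self):
        with pytest.raises(DataError):
            habituation_index([3.0])


class TestPtzResponse:
    def _series(self, pre_level, post_level, prot):
        onset = prot.onsets("dark_onset")[0]
        n = int(prot.length)
        vals = np.full(n, pre_level, float)
        vals[int(onset):] = post_level
        return _bins(vals)

    def test_treated_equals_baseline(self):
        prot = ptz_challenge(acclimation=60, spontaneous=60, light=120, dark=120)
        s = self._series(10.0, 20.0, prot)
        base, treated, norm = ptz_response(s, prot, s.copy())
        assert base == pytest.approx(10.0)
        assert norm == pytest.approx(0.0)

    def test_difference_normalization(self):
        prot = ptz_challenge(acclimation=60, spontaneous=60, light=120, dark=120)
        baseline = self._series(10.0, 30.0, prot)   # change +20
        treated = self._series(10.0, 60.0, prot)    # change +50
        base, tr, norm = ptz_response(treated, prot, baseline)
        assert (base, tr, norm) == (pytest.approx(20.0), pytest.approx(50.0),
                                    pytest.approx(30.0))

    def test_missing_baseline_is_error(self):
        prot = ptz_challenge(acclimation=60, spontaneous=60, light=120, dark=120)
        with pytest.raises(DataError, match="baseline"):
            ptz_response(self._series(1, 2, prot), prot, None)


def test_ratio_bounds_for_random_trajectories(rng):
    """All zone-ratio metrics stay inside [0, 1] for arbitrary bounded walks."""
    well = make_equal_area_well(12.0)
    tank = make_peripheral_band(80.0, 80.0)
    for _ in range(40):
        n = int(rng.integers(10, 300))
        t = np.arange(n) / 25.0
        xy = rng.normal(0, 1.2, (n, 2)).cumsum(axis=0)
        r = np.hypot(*xy.T)
        xy[r > 11.5] *= (11.5 / r[r > 11.5])[:, None]
        traj = make_traj(t, xy[:, 0], xy[:, 1])
        for za in (assign_zones(traj, well), assign_zones(traj, tank)):
            ratio = center_distance_ratio(za)
            if not math.isnan(ratio):
                assert 0.0 <= ratio <= 1.0
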