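"""Arena geometry: equal-area zones, exact covers, zone-assignment conservation."""

import numpy as np
import pandas as pd
import pytest

from swimmetrics.arena import (
    assign_zones,
    make_equal_area_well,
    make_peripheral_band,
    make_three_chamber,
)
from swimmetrics.errors import ConfigError, DataError

from conftest import make_traj


class TestEqualAreaWell:
    def test_inner_radius_is_r_over_sqrt2(self):
        well = make_equal_area_well(10.0)
        assert well.inner_radius == pytest.approx(10.0 / np.sqrt(2), abs=1e-12)
        assert abs(well.area("center") - well.area("outer")) / well.total_area < 1e-9

    def test_origin_is_center_zone(self):
        well = make_equal_area_well(10.0)
        assert well.zone_of(0.0, 0.0)[0] == "center"

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ConfigError):
            make_equal_area_well(0.0)

    def test_uniform_points_split_half_half(self, rng):
        # Monte-Carlo oracle for the equal-area rule
        well = make_equal_area_well(7.8)
        x, y = well.sample_uniform(10**6, rng)
        frac = np.mean(well.zone_of(x, y) == "center")
        assert frac == pytest.approx(0.5, abs=0.002)


class TestThreeChamber:
    def test_bisected_middle_chamber(self):
        tank = make_three_chamber(length=210.0, width=110.0, sector_fraction=0.5)
        assert tank.middle_length == pytest.approx(70.0)
        assert tank.sector_depth == pytest.approx(35.0)
        assert "neutral" not in tank.zones

    def test_point_next_to_left_divider_is_stimulus_sector(self):
        tank = make_three_chamber()
        assert tank.zone_of(-34.9, 0.0)[0] == "conspecific_sector"

    def test_uniform_points_split_between_sectors(self, rng):
        tank = make_three_chamber(sector_fraction=0.5)
        x, y = tank.sample_uniform(200_000, rng)
        frac = np.mean(tank.zone_of(x, y) == "conspecific_sector")
        assert frac == pytest.approx(0.5, abs=0.005)

    def test_neutral_zone_when_sectors_shallow(self):
        tank = make_three_chamber(sector_fraction=0.25)
        assert tank.zones == ("conspecific_sector", "neutral", "empty_sector")
        assert tank.zone_of(0.0, 0.0)[0] == "neutral"

    def test_overlapping_sectors_rejected(self):
        with pytest.raises(ConfigError):
            make_three_chamber(sector_fraction=0.6)


class TestPeripheralBand:
    def test_default_band_equalizes_areas(self):
        tank = make_peripheral_band(300.0, 300.0)
        # center square side = 300 - 2 * band ~ 212.13 mm
        assert 300.0 - 2 * tank.band == pytest.approx(300.0 / np.sqrt(2), abs=1e-9)
        assert tank.area("peripheral") == pytest.approx(tank.area("center"), abs=1e-6)

    def test_corner_point_is_peripheral(self):
        tank = make_peripheral_band(300.0, 300.0)
        assert tank.zone_of(149.0, 149.0)[0] == "peripheral"

    def test_partition_covers_tank(self):
        tank = make_peripheral_band(300.0, 200.0, band_fraction=0.2)
        assert tank.area("peripheral") + tank.area("center") == pytest.approx(
            tank.total_area
        )


@pytest.mark.parametrize(
    "arena",
    [
        make_equal_area_well(10.0),
        make_peripheral_band(300.0, 300.0),
        make_three_chamber(),
        make_three_chamber(sector_fraction=0.3),
    ],
    ids=["well", "tank", "chamber", "chamber_neutral"],
)
def test_zone_partition_is_exact_cover(arena, rng):
    """Every uniform point is claimed by exactly one declared zone."""
    x, y = arena.sample_uniform(100_000, rng)
    labels = arena.zone_of(x, y)
    assert set(np.unique(labels)) <= set(arena.zones)  # no stray labels
    # exactly-one is implicit in zone_of returning a single label; check the
    # declared areas tile the arena as well
    assert sum(arena.area(z) for z in arena.zones) == pytest.approx(arena.total_area)


class TestAssignZones:
    def test_trajectory_confined_to_center(self):
        well = make_equal_area_well(10.0)
        t = np.arange(0, 10, 0.04)
        traj = make_traj(t, 2.0 * np.cos(t), 2.0 * np.sin(t))
        za = assign_zones(traj, well)
        assert za.time_in("center") == pytest.approx(za.total_time())
        assert za.total_time() == pytest.approx(t[-1] - t[0])

    def test_diameter_chord_center_fraction(self):
        # straight path across the diameter: the center-zone distance
        # fraction equals 1/sqrt(2) (chord geometry), up to one-step
        # attribution error at each zone boundary
        well = make_equal_area_well(10.0)
        n = 2_000_001
        x = np.linspace(-10.0, 10.0, n)
        traj = make_traj(np.arange(n) / 25.0, x, np.zeros(n))
        za = assign_zones(traj, well)
        frac = za.distance_in("center") / za.total_distance()
        assert frac == pytest.approx(1 / np.sqrt(2), abs=1e-6)

    def test_conservation_against_brute_force(self, rng):
        well = make_equal_area_well(20.0)
        for _ in range(20):
            n = int(rng.integers(3, 400))
            t = np.arange(n) / 25.0
            xy = rng.normal(0, 1.0, (n, 2)).cumsum(axis=0)
            r = np.hypot(*xy.T)
            xy[r > 19.5] *= (19.5 / r[r > 19.5])[:, None]
            traj = make_traj(t, xy[:, 0], xy[:, 1])
            za = assign_zones(traj, well)
            totals = za.totals()
            # brute force: accumulate per sample
            steps = np.hypot(*np.diff(xy, axis=0).T)
            zones = well.zone_of(xy[:-1, 0], xy[:-1, 1])
            for z in well.zones:
                assert totals.loc[z, "distance"] == pytest.approx(
                    steps[zones == z].sum(), abs=1e-9
                )
            assert totals["time"].sum() == pytest.approx(t[-1] - t[0], abs=1e-9)
            assert totals["distance"].sum() == pytest.approx(steps.sum(), abs=1e-9)

    def test_rotation_invariance_in_circular_well(self, rng):
        well = make_equal_area_well(15.0)
        n = 500
        t = np.arange(n) / 25.0
        xy = rng.normal(0, 0.8, (n, 2)).cumsum(axis=0)
        r = np.hypot(*xy.T)
        xy[r > 14.5] *= (14.5 / r[r > 14.5])[:, None]
        za0 = assign_zones(make_traj(t, xy[:, 0], xy[:, 1]), well)
        phi = 1.234
        rot = xy @ np.array([[np.cos(phi), np.sin(phi)], [-np.sin(phi), np.cos(phi)]])
        za1 = assign_zones(make_traj(t, rot[:, 0], rot[:, 1]), well)
        pd.testing.assert_frame_equal(za0.totals(), za1.totals(), atol=1e-9, rtol=0)

    def test_point_far_outside_raises(self):
        well = make_equal_area_well(10.0)
        traj = make_traj([0.0, 0.04], [0.0, 25.0], [0.0, 0.0])
        with pytest.raises(DataError, match="outside the arena"):
            assign_zones(traj, well)

    def test_point_slightly_outside_clamped(self):
        well = make_equal_area_well(10.0)
        traj = make_traj([0.0, 0.04], [0.0, 10.3], [0.0, 0.0])
        za = assign_zones(traj, well, tolerance=0.5)
        assert np.hypot(za.samples["x"], za.samples["y"]).max() <= 10.0 + 1e-9
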