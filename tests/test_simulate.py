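"""Simulator contracts: determinism, boundary safety, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from swimmetrics.arena import make_equal_area_well, make_peripheral_band, make_three_chamber
from swimmetrics.io import bin_dataset
from swimmetrics.metrics import activity_change, center_distance_ratio
from swimmetrics.arena import assign_zones
from swimmetrics.protocol import asr, open_field
from swimmetrics.simulate import (
    GenotypePreset,
    SimulationSpec,
    default_presets,
    larval_ld_presets,
    null_presets,
    simulate,
)
from swimmetrics.protocol import windows_for


def _quiet(preset: GenotypePreset, **overrides) -> GenotypePreset:
    from dataclasses import replace

    return replace(preset, **overrides)


QUIET = _quiet(
    GenotypePreset(),
    wall_attraction=0.0,
    social_attraction=0.0,
    circling_rate=0.0,
    walling_bias=0.0,
    startle_gain=0.0,
    light_onset_gain=1.0,
    dark_onset_gain=1.0,
)


def test_same_seed_is_bit_identical():
    spec = SimulationSpec(
        arena=make_equal_area_well(8.0),
        protocol=open_field(duration=30, habituation=10),
        n_per_genotype=3,
        seed=9,
        speed_scale=0.1,
    )
    a = simulate(spec)
    b = simulate(spec)
    pd.testing.assert_frame_equal(a.tracks, b.tracks, check_exact=True)
    pd.testing.assert_frame_equal(a.subjects, b.subjects)


def test_subject_stream_stable_under_cohort_size():
    """A subject's trajectory must not depend on how many others are simulated."""
    kwargs = dict(
        arena=make_peripheral_band(300.0, 300.0),
        protocol=open_field(duration=20, habituation=10),
        seed=3,
    )
    small = simulate(SimulationSpec(n_per_genotype=1, **kwargs))
    large = simulate(SimulationSpec(n_per_genotype=5, **kwargs))
    sid = small.subject_ids[0]
    pd.testing.assert_frame_equal(
        small.track_for(sid), large.track_for(sid), check_exact=True
    )


@pytest.mark.parametrize(
    "arena",
    [
        make_equal_area_well(8.0),
        make_peripheral_band(300.0, 300.0),
        make_three_chamber(),
    ],
    ids=["well", "tank", "chamber"],
)
def test_trajectories_never_exit_arena(arena):
    spec = SimulationSpec(
        arena=arena,
        protocol=open_field(duration=60, habituation=10),
        n_per_genotype=4,
        seed=17,
        speed_scale=0.1 if hasattr(arena, "radius") else 1.0,
    )
    ds = simulate(spec)
    assert arena.contains(ds.tracks["x"].to_numpy(), ds.tracks["y"].to_numpy(),
                          tol=1e-9).all()


def test_mean_speed_recovers_base_speed():
    """At zero stimulus gains the realised mean speed tracks base_speed within 2%."""
    arena = make_peripheral_band(400.0, 400.0)
    spec = SimulationSpec(
        arena=arena,
        protocol=open_field(duration=120, habituation=10),
        n_per_genotype=10,
        seed=5,
        presets={"WT": QUIET},
    )
    ds = simulate(spec)
    speeds = []
    for sid in ds.subject_ids:
        traj = ds.track_for(sid)
        steps = np.hypot(np.diff(traj["x"]), np.diff(traj["y"]))
        speeds.append(steps.sum() / (traj["t"].iloc[-1] - traj["t"].iloc[0]))
    assert np.mean(speeds) == pytest.approx(QUIET.base_speed, rel=0.02)


def test_zero_startle_gain_gives_null_activity_change():
    prot = asr(adaptation=90, conditioning=90)
    arena = make_equal_area_well(8.0)
    spec = SimulationSpec(
        arena=arena, protocol=prot, n_per_genotype=50, seed=21,
        presets={"WT": QUIET}, speed_scale=0.1,
    )
    binned = bin_dataset(simulate(spec), 1.0)
    wins = windows_for(prot, "noise_onset")
    changes = [
        activity_change(binned.bins_for(sid), wins[0]) for sid in binned.subject_ids
    ]
    se = np.std(changes, ddof=1) / np.sqrt(len(changes))
    assert abs(np.mean(changes)) < 2 * se + 1e-9


def test_habituation_factor_recovery():
    """Mean startle responses across repeats recover habituation_factor ±0.1."""
    from dataclasses import replace

    h_true = 0.6
    preset = replace(QUIET, startle_gain=4.0, habituation_factor=h_true)
    prot = asr(adaptation=90, conditioning=90, cycles=3)
    spec = SimulationSpec(
        arena=make_equal_area_well(8.0), protocol=prot, n_per_genotype=50,
        seed=33, presets={"WT": preset}, speed_scale=0.1,
    )
    binned = bin_dataset(simulate(spec), 1.0)
    wins = windows_for(prot, "noise_onset")
    r = np.zeros(3)
    for sid in binned.subject_ids:
        bins = binned.bins_for(sid)
        r += [activity_change(bins, wp) for wp in wins]
    r /= len(binned.subject_ids)
    # responses follow r1 * h^(k-1): recover h from the geometric decay
    h_est = np.exp(np.polyfit([0, 1, 2], np.log(r), 1)[0])
    assert abs(h_est - h_true) < 0.1


def test_uniform_coverage_without_wall_attraction():
    """No wall attraction: center distance fraction of the equal-area well ~ 0.5."""
    arena = make_equal_area_well(8.0)
    spec = SimulationSpec(
        arena=arena,
        protocol=open_field(duration=300, habituation=10),
        n_per_genotype=20,
        seed=8,
        presets={"WT": QUIET},
        speed_scale=0.1,
    )
    ds = simulate(spec)
    ratios = [
        center_distance_ratio(assign_zones(ds.track_for(sid), arena))
        for sid in ds.subject_ids
    ]
    assert np.mean(ratios) == pytest.approx(0.5, abs=0.05)


def test_null_presets_are_identical():
    presets = null_presets()
    assert presets["WT"] == presets["mutant"]


def test_larval_pair_reverses_wall_attraction():
    default = default_presets()
    larval = larval_ld_presets()
    assert default["mutant"].wall_attraction < default["WT"].wall_attraction
    assert larval["mutant"].wall_attraction > larval["WT"].wall_attraction


def test_group_sem_tightens_with_n():
    """Quadrupling the cohort roughly halves the SEM of the mean velocity."""
    from swimmetrics.pipeline import run_open_field

    def sem_of(n):
        r = run_open_field(n_per_genotype=n, seed=10, duration=120, habituation=30)
        v = r.metrics.loc[r.metrics["genotype"] == "WT", "velocity"].to_numpy()
        return np.std(v, ddof=1) / np.sqrt(len(v))

    assert sem_of(32) < sem_of(8)
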