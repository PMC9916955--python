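"""Agent-based swimmer simulator.

Each subject is a correlated random walk inside a bounded arena: per time
step the heading receives a wrapped-normal increment, is relaxed toward the
nearest wall (thigmotaxis) and toward the stimulus-side divider (social
attraction), and the fish advances at a lognormally jittered speed.
Boundaries are reflective. Two transient behavioral states interrupt the
walk — tight circling at a fixed angular rate and fast wall-following —
entered at Poisson rates, which is what the stereotypy detectors score.

Stimulus kernels modulate speed at protocol onsets:

* light onset: multiplicative gain ``light_onset_gain`` decaying over ~10 s
  (below 1 = the normal visuomotor hypoactivity);
* dark onset: multiplicative gain ``dark_onset_gain`` decaying over ~30 s
  (above 1 = the normal dark-transition hyperactivity); PTZ in the bath
  suppresses this gain exponentially with concentration while adding a
  seizure-like drive ``ptz_sensitivity * concentration`` plus burst noise;
* noise onset: an additive startle burst decaying over ~3 s, scaled by
  ``habituation_factor**(k-1)`` on the k-th presentation.

Determinism: a single global seed; each subject's random stream is derived
from ``SeedSequence([seed, sha256(subject_id)])`` so a subject's trajectory
does not depend on cohort size or ordering. The same spec and seed yield a
bit-identical Dataset.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arena import Arena, ThreeChamberTank
from .errors import ConfigError
from .io import Dataset
from .protocol import Protocol

#: exponential suppression of the dark-onset response per mM PTZ
PTZ_SUPPRESSION_PER_MM = 0.3
#: stimulus kernel time constants (s)
TAU_LIGHT = 10.0
TAU_DARK = 30.0
TAU_STARTLE = 3.0
#: behavioral state parameters
CIRCLE_TURN_RATE = 150.0   # deg/s during a small-circle episode
CIRCLE_DURATION = 3.5      # s; longer than the detector window so loops register
CIRCLE_SPEED_FACTOR = 0.6  # loop radius = speed / turn rate
WALLING_DURATION = 6.0     # s
WALLING_RAIL_MM = 8.0      # distance to the wall held during a walling episode
NORMAL_STANDOFF_MM = 20.0  # ordinary thigmotactic swimming keeps this wall clearance
WALL_RANGE_FRACTION = 0.25  # e-folding range of wall attraction, x arena half-size


@dataclass(frozen=True)
class GenotypePreset:
    """Locomotor and stimulus-response parameters for one genotype.

    Speeds are adult-scale mm/s; assays on larvae pass a ``speed_scale`` in
    the :class:`SimulationSpec`. ``startle_gain`` is the peak burst speed in
    multiples of the (scaled) base speed. ``ptz_sensitivity`` is the
    additive dark-response gain per mM of PTZ.
    """

    base_speed: float = 45.0
    speed_cv: float = 0.35
    turning_sd: float = 14.0          # degrees per 1/25 s step
    wall_attraction: float = 0.9      # 1/s heading relaxation at the wall
    social_attraction: float = 0.8    # 1/s heading relaxation toward stimulus side
    light_onset_gain: float = 0.2
    dark_onset_gain: float = 2.5
    startle_gain: float = 3.0
    habituation_factor: float = 0.45
    circling_rate: float = 0.2        # episodes/min
    walling_bias: float = 0.3         # episodes/min
    ptz_sensitivity: float = 0.02     # gain/mM

    def __post_init__(self):
        if not 0 < self.habituation_factor <= 1:
            raise ConfigError("habituation_factor must be in (0, 1]")
        for name in ("base_speed", "speed_cv", "turning_sd", "wall_attraction",
                     "circling_rate", "walling_bias"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


def default_presets() -> dict[str, GenotypePreset]:
    """WT and shank2b-mutant presets reproducing the qualitative genotype
    contrasts of the adult and sensory assays: the mutant is hyperactive,
    hypo-thigmotactic (adult), socially indifferent, walling-prone, lacks
    light-onset hypoactivity, startles harder with weaker habituation, and
    responds more strongly to PTZ."""
    wt = GenotypePreset()
    mutant = replace(
        wt,
        base_speed=58.0,
        wall_attraction=0.25,
        social_attraction=0.0,
        light_onset_gain=1.15,
        startle_gain=6.0,
        habituation_factor=0.9,
        circling_rate=1.5,
        walling_bias=1.5,
        ptz_sensitivity=0.25,
    )
    return {"WT": wt, "mutant": mutant}


def larval_ld_presets() -> dict[str, GenotypePreset]:
    """Preset pair for the larval light/dark (center-ratio) assay.

    Larval thigmotaxis runs in the opposite direction to the adults': the
    mutant larva hugs the wall *more* (lower center distance ratio), so this
    pair swaps the wall-attraction ordering while keeping the mutant
    hyperactive."""
    base = default_presets()
    return {
        "WT": replace(base["WT"], wall_attraction=0.35),
        "mutant": replace(base["mutant"], wall_attraction=1.0),
    }


def null_presets() -> dict[str, GenotypePreset]:
    """Mutant preset identical to WT: the no-effect control condition."""
    wt = default_presets()["WT"]
    return {"WT": wt, "mutant": wt}


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to simulate one assay cohort deterministically."""

    arena: Arena
    protocol: Protocol
    n_per_genotype: int = 20
    fs: float = 25.0
    seed: int = 0
    presets: dict[str, GenotypePreset] = field(default_factory=default_presets)
    speed_scale: float = 1.0       # 1.0 adult, ~0.1 larva
    treatment: str = "none"        # recorded on subjects; PTZ conc parsed from protocol
    arena_id: str = "arena"
    id_prefix: str = "f"

    def __post_init__(self):
        if self.n_per_genotype < 1:
            raise ConfigError("n_per_genotype must be >= 1")
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")
        if not self.presets:
            raise ConfigError("at least one genotype preset is required")


def subject_seed(seed: int, subject_id: str) -> np.random.SeedSequence:
    """Stable per-subject seed stream: global seed + sha256 of the id."""
    digest = hashlib.sha256(subject_id.encode()).digest()
    sub = int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
    return np.random.SeedSequence([seed, sub])


def _ptz_concentration(protocol: Protocol) -> float:
    for phase in protocol.phases:
        m = re.fullmatch(r"PTZ@([0-9.]+)mM", phase.drug)
        if m:
            return float(m.group(1))
    return 0.0


def _stimulus_kernels(preset: GenotypePreset, protocol: Protocol,
                      t: np.ndarray, conc_mm: float):
    """Per-step multiplicative gain, additive startle drive (in units of the
    scaled base speed) and PTZ burst-noise amplitude."""
    mult = np.ones_like(t)
    add = np.zeros_like(t)
    burst = np.zeros_like(t)
    g_dark = (
        1.0
        + (preset.dark_onset_gain - 1.0) * np.exp(-PTZ_SUPPRESSION_PER_MM * conc_mm)
        + preset.ptz_sensitivity * conc_mm
    )
    n_noise = 0
    for stim in sorted(protocol.stimuli, key=lambda s: s.time):
        phase = protocol.phase_at(stim.time)
        in_phase = (t >= stim.time) & (t < phase.stop)
        rel = t - stim.time
        if stim.type == "light_onset":
            mult[in_phase] = 1.0 + (preset.light_onset_gain - 1.0) * np.exp(
                -rel[in_phase] / TAU_LIGHT
            )
        elif stim.type == "dark_onset":
            mult[in_phase] = 1.0 + (g_dark - 1.0) * np.exp(-rel[in_phase] / TAU_DARK)
            if conc_mm > 0:
                burst[in_phase] = 0.3 * preset.ptz_sensitivity * conc_mm
        elif stim.type == "noise_onset":
            n_noise += 1
            window = in_phase & (rel < 15.0)
            add[window] += (
                preset.startle_gain
                * preset.habituation_factor ** (n_noise - 1)
                * np.exp(-rel[window] / TAU_STARTLE)
            )
    return mult, add, burst


def simulate(spec: SimulationSpec) -> Dataset:
    """Run the simulator for every subject of every genotype in the spec.

    Returns a trajectory :class:`~swimmetrics.io.Dataset`; bin it with
    :func:`~swimmetrics.io.bin_dataset` for stimulus-locked analysis.
    """
    arena = spec.arena
    protocol = spec.protocol
    dt = 1.0 / spec.fs
    n_steps = int(round(protocol.length * spec.fs))
    t_grid = protocol.start + np.arange(n_steps + 1) / spec.fs
    conc = _ptz_concentration(protocol)

    genotypes = list(spec.presets)
    subject_rows = []
    subj_geno_idx = []
    subject_ids = []
    for gi, g in enumerate(genotypes):
        for k in range(spec.n_per_genotype):
            sid = f"{spec.id_prefix}_{g}_{k:03d}"
            subject_ids.append(sid)
            subj_geno_idx.append(gi)
            subject_rows.append(
                {"subject_id": sid, "genotype": g, "treatment": spec.treatment,
                 "arena_id": spec.arena_id}
            )
    n_subj = len(subject_ids)
    geno_idx = np.asarray(subj_geno_idx)

    # per-genotype stimulus kernels on the step grid (evaluated at step start)
    kernels = [
        _stimulus_kernels(spec.presets[g], protocol, t_grid[:-1], conc)
        for g in genotypes
    ]
    mult_g = np.stack([k[0] for k in kernels])   # (n_geno, n_steps)
    add_g = np.stack([k[1] for k in kernels])
    burst_g = np.stack([k[2] for k in kernels])

    # per-subject pre-generated random streams (stable under cohort changes)
    z_turn = np.empty((n_steps, n_subj))
    z_speed = np.empty((n_steps, n_subj))
    u_state = np.empty((n_steps, n_subj))
    z_extra = np.empty((n_steps, n_subj))
    x = np.empty(n_subj)
    y = np.empty(n_subj)
    theta = np.empty(n_subj)
    for j, sid in enumerate(subject_ids):
        rng = np.random.default_rng(subject_seed(spec.seed, sid))
        x[j], y[j] = (v[0] for v in arena.sample_uniform(1, rng))
        theta[j] = rng.uniform(-np.pi, np.pi)
        z_turn[:, j] = rng.standard_normal(n_steps)
        z_speed[:, j] = rng.standard_normal(n_steps)
        u_state[:, j] = rng.random(n_steps)
        z_extra[:, j] = rng.standard_normal(n_steps)

    # per-subject static parameters
    def _param(name):
        return np.asarray([getattr(spec.presets[g], name) for g in genotypes])[geno_idx]

    base = _param("base_speed") * spec.speed_scale
    sigma_ln = np.sqrt(np.log1p(_param("speed_cv") ** 2))
    turn_sd = np.deg2rad(_param("turning_sd"))
    wall_k = _param("wall_attraction")
    social_k = _param("social_attraction")
    p_circle = _param("circling_rate") * dt / 60.0
    p_wall = _param("walling_bias") * dt / 60.0

    if isinstance(arena, ThreeChamberTank):
        social_bearing = arena.stimulus_bearing
    else:
        social_bearing = None
        social_k = np.zeros_like(social_k)

    if hasattr(arena, "radius"):
        half_size = arena.radius
        wall_band = 0.3 * arena.radius
    elif isinstance(arena, ThreeChamberTank):
        half_size = min(arena.middle_length, arena.width) / 2
        wall_band = 0.3 * half_size
    else:
        half_size = min(arena.width, arena.height) / 2  # type: ignore[union-attr]
        wall_band = getattr(arena, "band", 0.3 * half_size)
    wall_range = WALL_RANGE_FRACTION * half_size

    circle_steps = int(round(CIRCLE_DURATION * spec.fs))
    wall_steps = int(round(WALLING_DURATION * spec.fs))
    omega_circle = np.deg2rad(CIRCLE_TURN_RATE) * dt

    xs = np.empty((n_steps + 1, n_subj))
    ys = np.empty((n_steps + 1, n_subj))
    xs[0] = x
    ys[0] = y

    state = np.zeros(n_subj, dtype=np.int8)   # 0 normal, 1 circling, 2 walling
    timer = np.zeros(n_subj, dtype=np.int64)
    sign = np.ones(n_subj)                    # turn/tangent direction of the episode

    def _wrap(a):
        return (a + np.pi) % (2 * np.pi) - np.pi

    for i in range(n_steps):
        wd = arena.wall_distance(x, y)
        wb = arena.wall_bearing(x, y)

        # state transitions
        timer -= 1
        ended = timer <= 0
        state[ended & (state != 0)] = 0
        normal = state == 0
        enter_c = normal & (u_state[i] < p_circle)
        enter_w = normal & ~enter_c & (u_state[i] < p_circle + p_wall) & (wd < 2 * wall_band)
        state[enter_c] = 1
        timer[enter_c] = circle_steps
        state[enter_w] = 2
        timer[enter_w] = wall_steps
        newly = enter_c | enter_w
        sign[newly] = np.where(z_extra[i][newly] >= 0, 1.0, -1.0)

        circling = state == 1
        walling = state == 2
        normal = state == 0

        # heading update; thigmotaxis = approach the wall, then follow it:
        # outside the band steer toward the wall (decaying with distance),
        # inside it align with the nearest tangent direction
        dtheta = turn_sd * z_turn[i]
        near = wd < wall_band
        t1 = wb + np.pi / 2
        choose_t1 = np.abs(_wrap(t1 - theta)) <= np.abs(_wrap(wb - np.pi / 2 - theta))
        tangent_t = np.where(choose_t1, t1, wb - np.pi / 2)
        wall_target = np.where(near, tangent_t, wb)
        # ordinary fish follow the wall at a standoff; only the walling
        # state presses against it
        standoff = min(NORMAL_STANDOFF_MM, 0.5 * wall_band)
        wall_target = np.where(wd < standoff, wb + np.pi, wall_target)
        alpha_wall = np.minimum(
            wall_k * dt * np.where(near, 1.0, np.exp(-(wd - wall_band) / wall_range)), 1.0
        )
        steer = alpha_wall * _wrap(wall_target - theta)
        if social_bearing is not None:
            steer = steer + np.minimum(social_k * dt, 1.0) * _wrap(social_bearing - theta)
        theta = np.where(normal, theta + dtheta + steer, theta)
        theta = np.where(circling, theta + sign * omega_circle, theta)
        if np.any(walling):
            tangent = wb + sign * np.pi / 2
            target = np.where(wd > WALLING_RAIL_MM, wb, tangent)
            theta = np.where(walling, theta + 0.5 * _wrap(target - theta), theta)
        theta = _wrap(theta)

        # speed
        gain = mult_g[geno_idx, i]
        lognorm = np.exp(sigma_ln * z_speed[i] - 0.5 * sigma_ln**2)
        v = base * gain * lognorm
        v = np.where(circling, CIRCLE_SPEED_FACTOR * base, v)
        v = np.where(walling, base, v)
        v = v + base * add_g[geno_idx, i]
        v = v + base * burst_g[geno_idx, i] * np.abs(z_extra[i])
        v = np.maximum(v, 0.0)

        x_new = x + v * dt * np.cos(theta)
        y_new = y + v * dt * np.sin(theta)
        inside = arena.contains(x_new, y_new)
        if not np.all(inside):
            rx, ry = arena.reflect(x_new, y_new)
            x_new = np.where(inside, x_new, rx)
            y_new = np.where(inside, y_new, ry)
            # heading follows the realised (reflected) displacement
            moved = ~inside & ((x_new != x) | (y_new != y))
            theta = np.where(moved, np.arctan2(y_new - y, x_new - x), theta)
        x, y = x_new, y_new
        xs[i + 1] = x
        ys[i + 1] = y

    tracks = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, n_steps + 1),
            "t": np.tile(t_grid, n_subj),
            "x": xs.T.ravel(),
            "y": ys.T.ravel(),
        }
    )
    subjects = pd.DataFrame(subject_rows)
    metadata = {
        "sampling_rate_hz": spec.fs,
        "seed": spec.seed,
        "protocol": protocol.name,
        "speed_scale": spec.speed_scale,
    }
    if conc > 0:
        metadata["ptz_mm"] = conc
    return Dataset(subjects=subjects, tracks=tracks, metadata=metadata)
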