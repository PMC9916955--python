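"""Assay orchestration: simulate -> metrics -> statistics -> report.

Each ``run_*`` function simulates one assay cohort, computes the per-subject
indices and the declared group comparisons, and returns an
:class:`AssayResult`. :func:`run_pipeline` drives any subset of assays from
a config mapping (or YAML file) into a results directory with CSV tables, a
manifest and a log; :func:`summarize` renders the results directory as a
human-readable report.

The seven headline genotype contrasts of the shank2b phenotype —
hyperactivity, reduced adult thigmotaxis, reduced social and kin
preference, increased walling, absent light-onset hypoactivity, enhanced
first startle with reduced habituation, and an increased PTZ-normalized
response — are declared in :data:`HEADLINE_CONTRASTS` and evaluated by
:func:`evaluate_headline`.
"""

from __future__ import annotations

import hashlib
import inspect
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as bm
from . import protocol as proto
from .arena import assign_zones, make_equal_area_well, make_peripheral_band, make_three_chamber
from .errors import ConfigError, DataError
from .io import Dataset, bin_dataset
from .simulate import (
    GenotypePreset,
    SimulationSpec,
    default_presets,
    larval_ld_presets,
    null_presets,
    simulate,
)
from .stats import ComparisonResult, mann_whitney, t_test
from .stereotypy import detect_stereotypy, summarize_events

log = logging.getLogger(__name__)

__version__ = "0.1.0"

#: larval subjects move at roughly a tenth of the adult scale
LARVAL_SPEED_SCALE = 0.1
WELL_RADIUS_MM = 8.0


@dataclass
class AssayResult:
    name: str
    metrics: pd.DataFrame                 # one row per subject
    comparisons: pd.DataFrame             # one row per declared test
    events: pd.DataFrame | None = None    # stereotypy events, where scored


def _result_row(assay: str, metric: str, res: ComparisonResult,
                groups: str = "mutant vs WT") -> dict:
    return {
        "assay": assay,
        "metric": metric,
        "groups": groups,
        "method": res.method,
        "direction": res.direction,
        "statistic": res.statistic,
        "df": res.df,
        "p_one": res.p_one,
        "p_two": res.p_two,
        "n_x": res.n_x,
        "n_y": res.n_y,
        "effect_direction": res.effect_direction,
    }


def _group_compare(df: pd.DataFrame, metric: str, assay: str,
                   test: str = "t", direction: str = "greater") -> dict:
    """Mutant-vs-WT comparison on one per-subject metric column."""
    x = df.loc[df["genotype"] == "mutant", metric].dropna().to_numpy()
    y = df.loc[df["genotype"] == "WT", metric].dropna().to_numpy()
    if test == "t":
        res = t_test(x, y, tails=1, direction=direction)
    elif test == "mw":
        res = mann_whitney(x, y, tails=1, direction=direction)
    else:
        raise ConfigError(f"unknown test {test!r}")
    return _result_row(assay, metric, res)


def _paired_rows(df: pd.DataFrame, assay: str, pre_col: str, post_col: str,
                 metric: str, direction: str) -> list[dict]:
    """Within-genotype paired t (post vs pre), one row per genotype."""
    rows = []
    for g, sub in df.groupby("genotype"):
        res = t_test(sub[post_col].to_numpy(), sub[pre_col].to_numpy(),
                     paired=True, tails=1, direction=direction)
        rows.append(_result_row(assay, metric, res, groups=f"{g}: post vs pre"))
    return rows


# ---------------------------------------------------------------------------
# assay runners


def run_open_field(presets: dict[str, GenotypePreset] | None = None,
                   n_per_genotype: int = 20, seed: int = 0,
                   duration: float = 1800.0, habituation: float = 300.0,
                   fs: float = 25.0, tank_size: float = 300.0) -> AssayResult:
    """Adult open field: velocity, peripheral-zone thigmotaxis, stereotypy."""
    presets = presets or default_presets()
    arena = make_peripheral_band(tank_size, tank_size)
    prot = proto.open_field(duration=duration, habituation=habituation)
    ds = simulate(SimulationSpec(arena=arena, protocol=prot, n_per_genotype=n_per_genotype,
                                 fs=fs, seed=seed, presets=presets, arena_id="open_tank"))
    window = prot.phase_window("test")
    rows = []
    all_events = []
    for sid, geno in zip(ds.subjects["subject_id"], ds.subjects["genotype"]):
        traj = ds.track_for(sid)
        za = assign_zones(traj, arena)
        ev = detect_stereotypy(traj, arena)
        ev = ev[(ev["start"] >= window[0]) & (ev["start"] < window[1])]
        summary = summarize_events(ev, duration=window[1] - window[0])
        rows.append({
            "subject_id": sid,
            "genotype": geno,
            "velocity": bm.velocity(traj=traj, window=window),
            "thigmotaxis": bm.thigmotaxis_adult(za, window=window),
            "walling_count": summary["walling_count"],
            "small_circle_count": summary["small_circle_count"],
            "stereotypy_time": summary["stereotypy_time"],
        })
        if len(ev):
            all_events.append(ev.assign(subject_id=sid))
    mt = pd.DataFrame(rows)
    comps = pd.DataFrame([
        _group_compare(mt, "velocity", "open_field", "t", "greater"),
        _group_compare(mt, "thigmotaxis", "open_field", "t", "less"),
        _group_compare(mt, "walling_count", "open_field", "mw", "greater"),
        _group_compare(mt, "small_circle_count", "open_field", "mw", "greater"),
    ])
    events = pd.concat(all_events, ignore_index=True) if all_events else None
    return AssayResult("open_field", mt, comps, events)


def _run_three_chamber(kin: bool, presets, n_per_genotype, seed,
                       duration, acclimation, fs) -> AssayResult:
    presets = presets or default_presets()
    labels = ("kin_sector", "nonkin_sector") if kin else ("conspecific_sector", "empty_sector")
    arena = make_three_chamber(sector_labels=labels)
    prot = proto.social_preference(duration=duration, acclimation=acclimation)
    name = "kin_preference" if kin else "social_preference"
    ds = simulate(SimulationSpec(arena=arena, protocol=prot, n_per_genotype=n_per_genotype,
                                 fs=fs, seed=seed, presets=presets, arena_id="three_chamber"))
    window = prot.phase_window("test")
    rows = []
    for sid, geno in zip(ds.subjects["subject_id"], ds.subjects["genotype"]):
        traj = ds.track_for(sid)
        za = assign_zones(traj, arena)
        time_ratio, dist_ratio = bm.social_preference(za, window=window)
        totals = za.totals(*window)
        rows.append({
            "subject_id": sid,
            "genotype": geno,
            "time_ratio": time_ratio,
            "distance_ratio": dist_ratio,
            "spi_time": bm.spi_from_zones(za, "time", window=window),
            "spi_distance": bm.spi_from_zones(za, "distance", window=window),
            "time_stimulus": float(totals.loc[labels[0], "time"]),
            "time_opposite": float(totals.loc[labels[1], "time"]),
        })
    mt = pd.DataFrame(rows)
    comp_rows = [
        _group_compare(mt, "time_ratio", name, "t", "less"),
        _group_compare(mt, "distance_ratio", name, "t", "less"),
        _group_compare(mt, "spi_time", name, "t", "less"),
        _group_compare(mt, "spi_distance", name, "t", "less"),
    ]
    # within-genotype paired preference: stimulus-side vs opposite-side time
    comp_rows += _paired_rows(mt, name, "time_opposite", "time_stimulus",
                              "time_stimulus_vs_opposite", "greater")
    return AssayResult(name, mt, pd.DataFrame(comp_rows))


def run_social_preference(presets=None, n_per_genotype: int = 20, seed: int = 0,
                          duration: float = 1800.0, acclimation: float = 300.0,
                          fs: float = 25.0) -> AssayResult:
    """Three-chamber conspecific preference: sector time/distance ratios."""
    return _run_three_chamber(False, presets, n_per_genotype, seed,
                              duration, acclimation, fs)


def run_kin_preference(presets=None, n_per_genotype: int = 20, seed: int = 0,
                       duration: float = 1800.0, acclimation: float = 300.0,
                       fs: float = 25.0) -> AssayResult:
    """Three-chamber kin-vs-non-kin preference: SPI on sector time/distance."""
    return _run_three_chamber(True, presets, n_per_genotype, seed,
                              duration, acclimation, fs)


def run_larval_light_dark(presets=None, n_per_genotype: int = 20, seed: int = 0,
                          habituation: float = 2700.0, phase_duration: float = 300.0,
                          fs: float = 25.0, well_radius: float = WELL_RADIUS_MM,
                          ) -> AssayResult:
    """Larval light/dark cycle: center distance ratio per phase (L0, D1, L1)."""
    presets = presets or larval_ld_presets()
    arena = make_equal_area_well(well_radius)
    prot = proto.larval_light_dark(habituation=habituation, phase_duration=phase_duration)
    ds = simulate(SimulationSpec(arena=arena, protocol=prot, n_per_genotype=n_per_genotype,
                                 fs=fs, seed=seed, presets=presets,
                                 speed_scale=LARVAL_SPEED_SCALE, arena_id="well"))
    rows = []
    for sid, geno in zip(ds.subjects["subject_id"], ds.subjects["genotype"]):
        za = assign_zones(ds.track_for(sid), arena)
        row = {"subject_id": sid, "genotype": geno}
        for label in ("L0", "D1", "L1"):
            row[f"center_ratio_{label}"] = bm.center_distance_ratio(
                za, window=prot.phase_window(label)
            )
        rows.append(row)
    mt = pd.DataFrame(rows)
    comps = pd.DataFrame([
        _group_compare(mt, f"center_ratio_{label}", "larval_light_dark", "t", "less")
        for label in ("L0", "D1", "L1")
    ])
    return AssayResult("larval_light_dark", mt, comps)


def _stimulus_changes(ds: Dataset, prot, stimulus: str, pre: float, post: float,
                      ) -> tuple[pd.DataFrame, list]:
    """Per-subject activity changes (and window means) for every onset."""
    wins = proto.windows_for(prot, stimulus, pre=pre, post=post)
    if not wins:
        raise DataError(f"protocol {prot.name} has no {stimulus} stimuli")
    binned = bin_dataset(ds, 1.0)
    rows = []
    for sid, geno in zip(ds.subjects["subject_id"], ds.subjects["genotype"]):
        bins = binned.bins_for(sid)
        row = {"subject_id": sid, "genotype": geno}
        for k, wp in enumerate(wins, start=1):
            row[f"pre_{k}"] = bm._window_mean(bins, *wp.pre)
            row[f"post_{k}"] = bm._window_mean(bins, *wp.post)
            row[f"change_{k}"] = row[f"post_{k}"] - row[f"pre_{k}"]
        row["mean_change"] = float(np.mean([row[f"change_{k}"] for k in range(1, len(wins) + 1)]))
        rows.append(row)
    return pd.DataFrame(rows), wins


def run_vmr(presets=None, n_per_genotype: int = 20, seed: int = 0,
            transition: str = "dark_to_light", adaptation: float = 3600.0,
            cycles: int = 3, conditioning: float = 300.0, post_phase: float | None = None,
            fs: float = 25.0, well_radius: float = WELL_RADIUS_MM) -> AssayResult:
    """Visuomotor response at illumination transitions.

    ``transition`` selects the paradigm: ``dark_to_light`` (5 min dark +
    15 s light cycles; the normal response is hypoactivity) or
    ``light_to_dark`` (5 min light + 5 min dark; the normal response is
    hyperactivity).
    """
    presets = presets or default_presets()
    if transition == "dark_to_light":
        prot = proto.vmr_dark_to_light(adaptation=adaptation, dark=conditioning,
                                       light=post_phase if post_phase else 15.0,
                                       cycles=cycles)
        stimulus = "light_onset"
        name = "vmr_dark_to_light"
    elif transition == "light_to_dark":
        prot = proto.vmr_light_to_dark(adaptation=adaptation, light=conditioning,
                                       dark=post_phase if post_phase else 300.0,
                                       cycles=cycles)
        stimulus = "dark_onset"
        name = "vmr_light_to_dark"
    else:
        raise ConfigError(f"unknown VMR transition {transition!r}")
    arena = make_equal_area_well(well_radius)
    ds = simulate(SimulationSpec(arena=arena, protocol=prot, n_per_genotype=n_per_genotype,
                                 fs=fs, seed=seed, presets=presets,
                                 speed_scale=LARVAL_SPEED_SCALE, arena_id="well"))
    mt, wins = _stimulus_changes(ds, prot, stimulus, pre=60.0, post=15.0)
    comp_rows = [
        _group_compare(mt, f"change_{k}", name, "t", "greater")
        for k in range(1, len(wins) + 1)
    ]
    comp_rows.append(_group_compare(mt, "mean_change", name, "t", "greater"))
    # canonical within-genotype response direction: hypoactivity at light
    # onset, hyperactivity at dark onset
    within = "less" if stimulus == "light_onset" else "greater"
    for k in range(1, len(wins) + 1):
        comp_rows += _paired_rows(mt, name, f"pre_{k}", f"post_{k}",
                                  f"post_vs_pre_{k}", within)
    return AssayResult(name, mt, pd.DataFrame(comp_rows))


def run_asr(presets=None, n_per_genotype: int = 20, seed: int = 0,
            adaptation: float = 3600.0, conditioning: float = 300.0,
            cycles: int = 3, fs: float = 25.0,
            well_radius: float = WELL_RADIUS_MM) -> AssayResult:
    """Acoustic startle: per-stimulus activity change and habituation index."""
    presets = presets or default_presets()
    prot = proto.asr(adaptation=adaptation, conditioning=conditioning, cycles=cycles)
    arena = make_equal_area_well(well_radius)
    ds = simulate(SimulationSpec(arena=arena, protocol=prot, n_per_genotype=n_per_genotype,
                                 fs=fs, seed=seed, presets=presets,
                                 speed_scale=LARVAL_SPEED_SCALE, arena_id="well"))
    mt, wins = _stimulus_changes(ds, prot, "noise_onset", pre=60.0, post=15.0)
    change_cols = [f"change_{k}" for k in range(1, len(wins) + 1)]
    mt["habituation_index"] = [
        bm.habituation_index(row) if row[0] > 0 else np.nan
        for row in mt[change_cols].to_numpy()
    ]
    comp_rows = [
        _group_compare(mt, col, "asr", "t", "greater") for col in change_cols
    ]
    comp_rows.append(_group_compare(mt, "habituation_index", "asr", "t", "less"))
    for k in range(1, len(wins) + 1):
        comp_rows += _paired_rows(mt, "asr", f"pre_{k}", f"post_{k}",
                                  f"post_vs_pre_{k}", "greater")
    return AssayResult("asr", mt, pd.DataFrame(comp_rows))


def run_ptz_challenge(presets=None, n_per_genotype: int = 20, seed: int = 0,
                      concentration_mm: float = 7.5, acclimation: float = 300.0,
                      spontaneous: float = 2700.0, light: float = 300.0,
                      dark: float = 300.0, fs: float = 25.0,
                      well_radius: float = WELL_RADIUS_MM) -> AssayResult:
    """PTZ light-to-dark challenge: each subject is recorded at baseline and
    again with PTZ in the bath; the response is the 60 s pre/post distance
    change at the dark onset, normalized as treated - baseline."""
    presets = presets or default_presets()
    arena = make_equal_area_well(well_radius)
    prot_base = proto.ptz_challenge(acclimation, spontaneous, light, dark, 0.0)
    prot_ptz = proto.ptz_challenge(acclimation, spontaneous, light, dark, concentration_mm)
    common = dict(arena=arena, n_per_genotype=n_per_genotype, fs=fs, seed=seed,
                  presets=presets, speed_scale=LARVAL_SPEED_SCALE, arena_id="well")
    ds_base = simulate(SimulationSpec(protocol=prot_base, treatment="vehicle", **common))
    ds_ptz = simulate(
        SimulationSpec(protocol=prot_ptz, treatment=f"PTZ@{concentration_mm:g}mM", **common)
    )
    bins_base = bin_dataset(ds_base, 1.0)
    bins_ptz = bin_dataset(ds_ptz, 1.0)
    rows = []
    for sid, geno in zip(ds_base.subjects["subject_id"], ds_base.subjects["genotype"]):
        baseline, treated, normalized = bm.ptz_response(
            bins_ptz.bins_for(sid), prot_ptz, bins_base.bins_for(sid), prot_base,
        )
        rows.append({
            "subject_id": sid,
            "genotype": geno,
            "baseline_change": baseline,
            "treated_change": treated,
            "normalized_change": normalized,
        })
    mt = pd.DataFrame(rows)
    comp_rows = [_group_compare(mt, "normalized_change", "ptz_challenge", "t", "greater")]
    comp_rows += _paired_rows(mt, "ptz_challenge", "baseline_change", "treated_change",
                              "treated_vs_baseline", "greater")
    return AssayResult("ptz_challenge", mt, pd.DataFrame(comp_rows))


ASSAY_RUNNERS = {
    "open_field": run_open_field,
    "social_preference": run_social_preference,
    "kin_preference": run_kin_preference,
    "larval_light_dark": run_larval_light_dark,
    "vmr_dark_to_light": lambda **kw: run_vmr(transition="dark_to_light", **kw),
    "vmr_light_to_dark": lambda **kw: run_vmr(transition="light_to_dark", **kw),
    "asr": run_asr,
    "ptz_challenge": run_ptz_challenge,
}

_RUNNER_SIGNATURES = {
    "open_field": run_open_field,
    "social_preference": run_social_preference,
    "kin_preference": run_kin_preference,
    "larval_light_dark": run_larval_light_dark,
    "vmr_dark_to_light": run_vmr,
    "vmr_light_to_dark": run_vmr,
    "asr": run_asr,
    "ptz_challenge": run_ptz_challenge,
}


# ---------------------------------------------------------------------------
# headline contrasts

#: the seven genotype contrasts; each entry lists the (assay, metric)
#: comparisons that must all reach one-sided significance
HEADLINE_CONTRASTS: list[tuple[str, list[tuple[str, str]]]] = [
    ("hyperactivity", [("open_field", "velocity")]),
    ("reduced_adult_thigmotaxis", [("open_field", "thigmotaxis")]),
    ("reduced_social_and_kin_preference",
     [("social_preference", "time_ratio"), ("kin_preference", "spi_time")]),
    ("increased_walling", [("open_field", "walling_count")]),
    ("absent_light_onset_hypoactivity", [("vmr_dark_to_light", "mean_change")]),
    ("enhanced_startle_reduced_habituation",
     [("asr", "change_1"), ("asr", "habituation_index")]),
    ("increased_ptz_response", [("ptz_challenge", "normalized_change")]),
]


def evaluate_headline(comparisons: pd.DataFrame,
                      metrics: pd.DataFrame | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Score the seven headline contrasts against a comparisons table.

    A contrast passes when every member comparison is one-sided significant
    at ``alpha`` with the observed effect in the declared direction. The
    light-onset contrast additionally requires the sign pattern that defines
    it: WT mean activity change negative (hypoactivity), mutant mean
    non-negative — checked from the per-subject metrics when provided.
    """
    between = comparisons[comparisons["groups"] == "mutant vs WT"]
    rows = []
    for name, members in HEADLINE_CONTRASTS:
        ps = []
        ok = True
        for assay, metric in members:
            sel = between[(between["assay"] == assay) & (between["metric"] == metric)]
            if sel.empty:
                ok = False
                ps.append(np.nan)
                continue
            row = sel.iloc[0]
            ps.append(float(row["p_one"]))
            ok = ok and row["p_one"] < alpha and row["effect_direction"] == row["direction"]
        if name == "absent_light_onset_hypoactivity" and metrics is not None:
            vmr = metrics[metrics["assay"] == "vmr_dark_to_light"]
            if len(vmr):
                wt_mean = vmr.loc[vmr["genotype"] == "WT", "mean_change"].astype(float).mean()
                mut_mean = vmr.loc[vmr["genotype"] == "mutant", "mean_change"].astype(float).mean()
                ok = ok and wt_mean < 0 and mut_mean >= 0
            else:
                ok = False
        rows.append({
            "contrast": name,
            "n_tests": len(members),
            "max_p_one": (float(np.nanmax(ps))
                          if ps and np.isfinite(ps).any() else np.nan),
            "passed": bool(ok),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config-driven pipeline

#: desk-scale assay parameters: analysed phases at protocol durations, the
#: signal-free adaptation/habituation periods shortened, recordings trimmed
DESK_SCALE_ASSAYS: dict[str, dict] = {
    "open_field": {"duration": 600, "habituation": 60},
    "social_preference": {"duration": 600, "acclimation": 60},
    "kin_preference": {"duration": 600, "acclimation": 60},
    "larval_light_dark": {"habituation": 120},
    "vmr_dark_to_light": {"adaptation": 120},
    "vmr_light_to_dark": {"adaptation": 120, "conditioning": 120, "post_phase": 120},
    "asr": {"adaptation": 120},
    "ptz_challenge": {"acclimation": 60, "spontaneous": 120},
}

_PRESET_MODES = {"default": default_presets, "null": null_presets}

_TOP_KEYS = {"seed", "out", "n_per_genotype", "presets", "assays", "name"}


def demo_config(seed: int = 0, out: str | Path = "results/demo") -> dict:
    """Desk-scale demo configuration covering every assay."""
    return {
        "name": "demo",
        "seed": seed,
        "out": str(out),
        "n_per_genotype": 20,
        "presets": "default",
        "assays": {name: dict(params) for name, params in DESK_SCALE_ASSAYS.items()},
    }


def _validate_config(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ConfigError("pipeline config must be a mapping")
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "assays" not in config or not config["assays"]:
        raise ConfigError("config needs a non-empty 'assays' mapping")
    bad = set(config["assays"]) - set(ASSAY_RUNNERS)
    if bad:
        raise ConfigError(
            f"unknown assay names: {sorted(bad)} (known: {sorted(ASSAY_RUNNERS)})"
        )
    preset_mode = config.get("presets", "default")
    if preset_mode not in _PRESET_MODES:
        raise ConfigError(f"presets must be one of {sorted(_PRESET_MODES)}")
    for name, params in config["assays"].items():
        params = params or {}
        sig = inspect.signature(_RUNNER_SIGNATURES[name])
        allowed = set(sig.parameters) - {"presets", "n_per_genotype", "seed", "transition"}
        extra = set(params) - allowed
        if extra:
            raise ConfigError(
                f"assay {name!r}: unknown parameters {sorted(extra)} "
                f"(allowed: {sorted(allowed)})"
            )
    return config


def load_config(path_or_dict: dict | str | Path) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        p = Path(path_or_dict)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        config = yaml.safe_load(p.read_text())
    else:
        config = path_or_dict
    return _validate_config(config)


def run_assays(config: dict) -> tuple[list[AssayResult], dict]:
    """Run every assay in the config; returns results and the manifest dict."""
    config = _validate_config(config)
    seed = int(config.get("seed", 0))
    n = int(config.get("n_per_genotype", 20))
    preset_mode = config.get("presets", "default")
    base_presets = _PRESET_MODES[preset_mode]()

    results = []
    for idx, (name, params) in enumerate(sorted(config["assays"].items())):
        params = dict(params or {})
        assay_seed = (seed * 1009 + 7919 * idx + idx) % (2**31)
        if name == "larval_light_dark":
            # stage-specific thigmotaxis direction: the larval pair swaps the
            # wall-attraction ordering (null mode keeps the null pair)
            presets = larval_ld_presets() if preset_mode == "default" else base_presets
        else:
            presets = base_presets
        log.info("running assay %s (seed %d, n=%d/genotype)", name, assay_seed, n)
        res = ASSAY_RUNNERS[name](presets=presets, n_per_genotype=n,
                                  seed=assay_seed, **params)
        results.append(res)

    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "name": config.get("name", "pipeline"),
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "n_per_genotype": n,
        "presets": preset_mode,
        "assays": sorted(config["assays"]),
        "versions": {
            "swimmetrics": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    return results, manifest


def collect(results: list[AssayResult]) -> dict[str, pd.DataFrame]:
    """Concatenate per-assay tables into the pipeline's three output tables."""
    metrics_long = []
    for r in results:
        m = r.metrics.melt(id_vars=["subject_id", "genotype"],
                           var_name="metric", value_name="value")
        m.insert(0, "assay", r.name)
        metrics_long.append(m)
    comparisons = pd.concat([r.comparisons for r in results], ignore_index=True)
    events = [r.events.assign(assay=r.name) for r in results if r.events is not None]
    return {
        "metrics": pd.concat(metrics_long, ignore_index=True),
        "comparisons": comparisons,
        "events": (pd.concat(events, ignore_index=True) if events
                   else pd.DataFrame(columns=["type", "start", "end", "subject_id", "assay"])),
    }


def metrics_wide(results: list[AssayResult]) -> pd.DataFrame:
    """Per-subject metric rows in wide form with an assay column."""
    frames = []
    for r in results:
        m = r.metrics.copy()
        m.insert(0, "assay", r.name)
        frames.append(m)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: dict | str | Path, out: str | Path | None = None) -> Path:
    """Run the configured assays and write the results directory.

    Writes ``metrics.csv`` (long form, one row per subject x metric),
    ``comparisons.csv``, ``stereotypy_events.csv``, ``contrasts.csv`` (the
    headline-contrast scoreboard), ``manifest.json`` and ``pipeline.log``.
    Identical config and seed reproduce byte-identical CSV outputs.
    """
    config = load_config(config)
    out_dir = Path(out or config.get("out", "results"))
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("swimmetrics")
    root.addHandler(handler)
    try:
        results, manifest = run_assays(config)
        tables = collect(results)
        wide = metrics_wide(results)
        float_fmt = "%.10g"
        tables["metrics"].to_csv(out_dir / "metrics.csv", index=False, float_format=float_fmt)
        tables["comparisons"].to_csv(out_dir / "comparisons.csv", index=False,
                                     float_format=float_fmt)
        tables["events"].to_csv(out_dir / "stereotypy_events.csv", index=False,
                                float_format=float_fmt)
        contrasts = evaluate_headline(tables["comparisons"], wide)
        contrasts.to_csv(out_dir / "contrasts.csv", index=False, float_format=float_fmt)
        manifest["outputs"] = sorted(
            p.name for p in out_dir.iterdir() if p.suffix in (".csv", ".json")
        )
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.info("pipeline finished: %s", out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out_dir


# ---------------------------------------------------------------------------
# reporting


def _sem(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    if len(values) < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def summarize(results_dir: str | Path) -> str:
    """Render a results directory as a plain-text report.

    Per assay and metric: group means +/- SEM with n, then the declared
    test and its p-values; a headline-contrast scoreboard at the end when
    both genotypes are present.
    """
    results_dir = Path(results_dir)
    mpath = results_dir / "metrics.csv"
    if not mpath.exists():
        raise DataError(f"no metrics.csv under {results_dir}")
    metrics = pd.read_csv(mpath)
    if metrics.empty:
        log.warning("empty results in %s", results_dir)
        return "(no results)\n"
    cpath = results_dir / "comparisons.csv"
    comparisons = pd.read_csv(cpath) if cpath.exists() else pd.DataFrame()

    lines = [f"swimmetrics report — {results_dir.name}", "=" * 60]
    genotypes = sorted(metrics["genotype"].unique())
    for assay, sub in metrics.groupby("assay"):
        lines.append(f"\n[{assay}]")
        for metric, vals in sub.groupby("metric"):
            cells = []
            for g in genotypes:
                v = vals.loc[vals["genotype"] == g, "value"].to_numpy(float)
                v = v[np.isfinite(v)]
                if len(v) == 0:
                    continue
                cells.append(f"{g}: {np.mean(v):.4g} ± {_sem(v):.3g} (n={len(v)})")
            lines.append(f"  {metric:<28s} " + " | ".join(cells))
        if len(comparisons):
            for _, row in comparisons[(comparisons["assay"] == assay)
                                      & (comparisons["groups"] == "mutant vs WT")].iterrows():
                star = "*" if row["p_one"] < 0.05 else " "
                lines.append(
                    f"    {row['metric']:<26s} {row['method']}, {row['direction']}: "
                    f"p(one)={row['p_one']:.4g}, p(two)={row['p_two']:.4g} {star}"
                )
    if len(genotypes) >= 2 and len(comparisons):
        wide_path = results_dir / "contrasts.csv"
        if wide_path.exists():
            contrasts = pd.read_csv(wide_path)
            lines.append("\nHeadline genotype contrasts")
            lines.append("-" * 60)
            for _, row in contrasts.iterrows():
                status = "PASS" if row["passed"] else "FAIL"
                lines.append(f"  {row['contrast']:<40s} {status}  (max p {row['max_p_one']:.3g})")
    else:
        lines.append("\n(single-genotype input: comparisons skipped)")
    return "\n".join(lines) + "\n"
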