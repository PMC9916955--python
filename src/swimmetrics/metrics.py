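"""Per-subject behavioral indices.

All functions are pure: they take a :class:`~swimmetrics.arena.ZoneAssignment`
(for zone-restricted quantities), a binned activity series (for
stimulus-locked quantities) or plain numbers, and return floats. A metric
whose denominator is zero is *undefined* and returned as ``nan`` — never
silently coerced to 0.

Conventions
-----------
* ``center_distance_ratio`` is distance-in-center / total-distance per
  analysis window; the larval "thigmotaxis" reading is ``1 - ratio``.
* Adult ``thigmotaxis`` is the peripheral-zone distance fraction.
* ``activity_change`` is mean post-stimulus bin activity minus mean
  pre-stimulus bin activity (signed; mm per bin for distance bins).
* The social preference index (SPI) is ``(A - B) / (A + B)`` for a
  stimulus-side metric A and opposite-side metric B, in [-1, 1].
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .arena import ZoneAssignment
from .errors import DataError
from .protocol import StimulusWindowPair

Window = tuple[float, float] | None


def _bounds(window: Window) -> tuple[float | None, float | None]:
    return (None, None) if window is None else (window[0], window[1])


def center_distance_ratio(za: ZoneAssignment, window: Window = None,
                          center_zone: str = "center") -> float:
    """Distance moved in the center zone over distance moved in the whole zone.

    Undefined (``nan``) when the subject did not move during the window.
    """
    t0, t1 = _bounds(window)
    totals = za.totals(t0, t1)
    whole = float(totals["distance"].sum())
    if whole <= 0:
        return math.nan
    return float(totals.loc[center_zone, "distance"]) / whole


def thigmotaxis_larval(za: ZoneAssignment, window: Window = None) -> float:
    """Wall preference of a larva in an equal-area well: 1 - center ratio."""
    r = center_distance_ratio(za, window)
    return 1.0 - r if not math.isnan(r) else math.nan


def thigmotaxis_adult(za: ZoneAssignment, window: Window = None,
                      peripheral_zone: str = "peripheral") -> float:
    """Distance moved in the peripheral zone over distance moved in the whole zone."""
    t0, t1 = _bounds(window)
    totals = za.totals(t0, t1)
    whole = float(totals["distance"].sum())
    if whole <= 0:
        return math.nan
    return float(totals.loc[peripheral_zone, "distance"]) / whole


def social_preference(za: ZoneAssignment, total_time: float | None = None,
                      window: Window = None,
                      sector: str | None = None) -> tuple[float, float]:
    """(time_ratio, distance_ratio) toward the stimulus-side sector.

    ``time_ratio`` divides by the total test time (the window length, or
    ``total_time`` when given); ``distance_ratio`` divides by the total
    distance traveled. Ratios are in [0, 1]; undefined denominators give nan.
    """
    t0, t1 = _bounds(window)
    totals = za.totals(t0, t1)
    if sector is None:
        sector = za.arena.sector_labels[0]  # type: ignore[union-attr]
    if total_time is None:
        total_time = (t1 - t0) if window is not None else za.total_time()
    t_sector = float(totals.loc[sector, "time"])
    d_sector = float(totals.loc[sector, "distance"])
    d_total = float(totals["distance"].sum())
    time_ratio = t_sector / total_time if total_time > 0 else math.nan
    dist_ratio = d_sector / d_total if d_total > 0 else math.nan
    return time_ratio, dist_ratio


def spi(metric_a: float, metric_b: float) -> float:
    """Social preference index (A - B) / (A + B); nan when A + B = 0.

    A is the stimulus-side (conspecific/kin) metric, B the opposite-side
    (empty/non-kin) metric; either distances or times may be used as long as
    both sides use the same quantity.
    """
    total = metric_a + metric_b
    if total <= 0:
        return math.nan
    return (metric_a - metric_b) / total


def spi_from_zones(za: ZoneAssignment, quantity: str = "time",
                   window: Window = None) -> float:
    """SPI computed directly from the two sectors of a three-chamber assignment."""
    t0, t1 = _bounds(window)
    totals = za.totals(t0, t1)
    a_label, b_label = za.arena.sector_labels  # type: ignore[union-attr]
    col = {"time": "time", "distance": "distance"}[quantity]
    return spi(float(totals.loc[a_label, col]), float(totals.loc[b_label, col]))


def velocity(traj: pd.DataFrame | None = None, bins: pd.DataFrame | None = None,
             window: Window = None) -> float:
    """Mean speed (mm/s): total distance over window length.

    Accepts a trajectory (steps attributed to the window containing their
    start time) or a binned series; for 1 s bins this equals the mean of
    per-bin distances.
    """
    if traj is not None:
        t = traj["t"].to_numpy(float)
        if len(t) < 2:
            return 0.0
        steps = np.hypot(np.diff(traj["x"].to_numpy(float)),
                         np.diff(traj["y"].to_numpy(float)))
        start = t[:-1]
        if window is None:
            length = t[-1] - t[0]
            total = steps.sum()
        else:
            t0, t1 = window
            length = t1 - t0
            mask = (start >= t0) & (start < t1)
            total = steps[mask].sum()
        if length <= 0:
            raise DataError("velocity window has non-positive length")
        return float(total / length)
    if bins is not None:
        sel = bins
        if window is not None:
            t0, t1 = window
            sel = bins[(bins["t_start"] >= t0) & (bins["t_start"] < t1)]
        span = float(sel["dt"].sum())
        if span <= 0:
            raise DataError("velocity window contains no bins")
        return float(sel["distance"].sum() / span)
    raise DataError("velocity needs a trajectory or a binned series")


def _window_mean(bins: pd.DataFrame, start: float, stop: float,
                 value: str = "distance") -> float:
    dt = float(bins["dt"].iloc[0])
    t0 = bins["t_start"].to_numpy(float)
    mask = (t0 >= start - 1e-9) & (t0 < stop - 1e-9)
    expected = int(round((stop - start) / dt))
    if int(mask.sum()) < max(expected, 1):
        raise DataError(
            f"series does not cover window [{start:g}, {stop:g}) "
            f"({int(mask.sum())} of {expected} bins present)"
        )
    return float(bins.loc[mask, value].mean())


def activity_change(bins: pd.DataFrame, wp: StimulusWindowPair,
                    value: str = "distance") -> float:
    """Mean post-stimulus bin activity minus mean pre-stimulus bin activity.

    Signed; positive means the stimulus increased activity. Raises
    :class:`DataError` when the series does not cover both windows.
    """
    pre = _window_mean(bins, *wp.pre, value=value)
    post = _window_mean(bins, *wp.post, value=value)
    return post - pre


def habituation_index(responses: list[float] | np.ndarray) -> float:
    """Fractional decline of the stimulus response across repetitions.

    ``(r_1 - r_last) / r_1``: positive values indicate habituation, 0 none,
    negative sensitization. Undefined (nan) unless the first response is
    positive; needs at least two responses.
    """
    r = np.asarray(responses, float)
    if len(r) < 2:
        raise DataError("habituation index needs at least two responses")
    if r[0] <= 0:
        return math.nan
    return float((r[0] - r[-1]) / r[0])


def ptz_response(bins_treated: pd.DataFrame, protocol, bins_baseline: pd.DataFrame,
                 baseline_protocol=None, pre: float = 60.0, post: float = 60.0,
                 mode: str = "difference") -> tuple[float, float, float]:
    """Light-to-dark activity change before and after PTZ exposure.

    Both recordings must follow the light-to-dark challenge schedule; the
    response is the distance-change in the ``pre``/``post`` seconds around
    the dark onset. ``normalized`` is ``treated - baseline`` (default) or
    ``treated / baseline`` with ``mode='ratio'``.

    Returns ``(baseline_change, treated_change, normalized)``.
    """
    from .protocol import windows_for  # local import to avoid cycle at module load

    if bins_baseline is None:
        raise DataError("PTZ response requires a baseline recording")
    if baseline_protocol is None:
        baseline_protocol = protocol
    wins_t = windows_for(protocol, "dark_onset", pre=pre, post=post)
    wins_b = windows_for(baseline_protocol, "dark_onset", pre=pre, post=post)
    if not wins_t or not wins_b:
        raise DataError("protocol defines no light-to-dark transition")
    treated_change = activity_change(bins_treated, wins_t[0])
    baseline_change = activity_change(bins_baseline, wins_b[0])
    if mode == "difference":
        normalized = treated_change - baseline_change
    elif mode == "ratio":
        normalized = treated_change / baseline_change if baseline_change != 0 else math.nan
    else:
        raise DataError(f"unknown PTZ normalization mode {mode!r}")
    return baseline_change, treated_change, normalized
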