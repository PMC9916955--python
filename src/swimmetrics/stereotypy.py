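"""Algorithmic detection of stereotyped swimming patterns.

Two repetitive patterns scored in the adult open field are detected from
the trajectory alone:

* **small circling** — tight loops: a segment accumulating at least
  ``min_total_turn`` degrees of unsigned heading change within a short
  window while staying inside a small bounding circle;
* **walling** — sustained fast wall-following: an interval spent inside the
  peripheral wall band at or above a minimum speed for a minimum duration.

The original scoring was done by a blinded human rater from trajectory
plots; the detectors below are an explicit, reproducible operationalization
with configurable thresholds, not a re-implementation of the human
criteria. Detections are invariant under time reversal of the trajectory.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arena import RectangularTank
from .errors import ConfigError, DataError

EVENT_COLUMNS = ["type", "start", "end"]

#: default walling band: roughly one adult body depth against the wall —
#: much tighter than the thigmotaxis zone, which ordinary peripheral
#: swimming occupies without "walling"
WALLING_BAND_MM = 12.0


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=EVENT_COLUMNS).astype(
        {"type": str, "start": float, "end": float}
    )


def _headings(x: np.ndarray, y: np.ndarray, noise_floor: float) -> np.ndarray:
    """Per-step headings; steps shorter than ``noise_floor`` inherit the
    previous heading so jitter does not register as turning."""
    dx = np.diff(x)
    dy = np.diff(y)
    theta = np.arctan2(dy, dx)
    short = np.hypot(dx, dy) < noise_floor
    for i in range(len(theta)):  # carry-forward; loop is fine at these sizes
        if short[i] and i > 0:
            theta[i] = theta[i - 1]
    return theta


def detect_small_circles(traj: pd.DataFrame,
                         min_total_turn: float = 330.0,
                         max_loop_diameter: float | None = None,
                         window: float = 3.0,
                         arena=None,
                         noise_floor: float = 0.05) -> pd.DataFrame:
    """Detect tight-loop (small circling) episodes.

    A segment is a loop if it accumulates ``min_total_turn`` degrees of net
    heading change (the magnitude of the signed cumulative turn, so jitter
    cancels and only consistent rotation counts) within at most ``window``
    seconds while its points fit in a circle of diameter at most
    ``max_loop_diameter`` (default: one sixth of the arena's smaller side).
    The shortest such segment starting at each sample is tested, so a brief
    tight loop flanked by fast straight swimming is still detected.
    Overlapping detections are merged into episodes; an episode with T
    degrees of accumulated turn yields ``1 + floor((T - min_total_turn)/360)``
    events, i.e. roughly one event per full revolution.

    Returns a DataFrame ``type, start, end`` (type = ``"small_circle"``).
    """
    if max_loop_diameter is None:
        if arena is None or not hasattr(arena, "width"):
            raise ConfigError("max_loop_diameter or a rectangular arena is required")
        max_loop_diameter = min(arena.width, arena.height) / 6.0
    t = traj["t"].to_numpy(float)
    x = traj["x"].to_numpy(float)
    y = traj["y"].to_numpy(float)
    n = len(t)
    if n < 3 or t[-1] - t[0] < window:
        return _empty_events()

    theta = _headings(x, y, noise_floor)
    dtheta = np.angle(np.exp(1j * np.diff(theta)))  # signed, wrapped to (-pi, pi]
    # signed cumulative turn "at sample j": heading change between the two
    # steps adjacent to sample j (j = 1 .. n-2)
    turn_at = np.zeros(n)
    turn_at[1:n - 1] = dtheta
    cum = np.cumsum(turn_at)
    min_turn_rad = np.deg2rad(min_total_turn)

    # net turn of the segment [a, b] (samples) = |cum[b-1] - cum[a]|;
    # scan, for each start a, the deviation of cum within the next W samples
    W = max(int(round(window / float(np.median(np.diff(t))))), 2)
    W = min(W, n)
    # pad so segments starting near the end (truncated by the recording) are
    # still scanned
    cum_pad = np.r_[cum, np.full(W - 1, cum[-1])]
    sw = np.lib.stride_tricks.sliding_window_view(cum_pad, W)
    dev = np.abs(sw - cum[:, None])
    candidates = np.flatnonzero(dev.max(axis=1) >= min_turn_rad)

    marked = np.zeros(n, dtype=bool)
    for a in candidates:
        j = int(np.argmax(dev[a] >= min_turn_rad))  # first threshold crossing
        b = min(a + j + 1, n - 1)
        cx = x[a:b + 1].mean()
        cy = y[a:b + 1].mean()
        diameter = 2.0 * np.hypot(x[a:b + 1] - cx, y[a:b + 1] - cy).max()
        if diameter <= max_loop_diameter:
            marked[a:b + 1] = True

    return _events_from_marks(t, marked, cum, min_turn_rad)


def _events_from_marks(t, marked, cum, min_turn_rad) -> pd.DataFrame:
    rows = []
    n = len(t)
    edges = np.flatnonzero(np.diff(np.r_[False, marked, False]))
    for a, b_excl in zip(edges[::2], edges[1::2]):
        b = b_excl - 1
        turn = abs(cum[max(b - 1, 0)] - cum[a])
        if turn < min_turn_rad:
            continue
        n_events = 1 + int(np.floor((turn - min_turn_rad) / (2 * np.pi)))
        bounds = np.linspace(t[a], t[min(b, n - 1)], n_events + 1)
        for k in range(n_events):
            rows.append({"type": "small_circle", "start": bounds[k], "end": bounds[k + 1]})
    if not rows:
        return _empty_events()
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def detect_walling(traj: pd.DataFrame, arena: RectangularTank,
                   band: float | None = None,
                   min_duration: float = 2.0,
                   min_speed: float = 5.0,
                   merge_gap: float = 0.5) -> pd.DataFrame:
    """Detect sustained wall-following (walling) episodes.

    An event is a maximal interval during which the fish stays within
    ``band`` mm of a wall (default: one body depth, or the arena's
    peripheral band if narrower) while moving at ``min_speed`` mm/s or
    faster, lasting at least ``min_duration`` s. Interruptions shorter than
    ``merge_gap`` s are bridged.

    Returns a DataFrame ``type, start, end`` (type = ``"walling"``).
    """
    if band is None:
        if not hasattr(arena, "band"):
            raise ConfigError("walling detection needs a rectangular arena or explicit band")
        band = min(arena.band, WALLING_BAND_MM)
    t = traj["t"].to_numpy(float)
    x = traj["x"].to_numpy(float)
    y = traj["y"].to_numpy(float)
    n = len(t)
    if n < 2:
        return _empty_events()

    in_band = arena.wall_distance(x, y) <= band
    # centred speed estimate (symmetric under time reversal)
    d = np.hypot(np.diff(x), np.diff(y))
    v = np.empty(n)
    v[0] = d[0] / (t[1] - t[0])
    v[-1] = d[-1] / (t[-1] - t[-2])
    if n > 2:
        v[1:-1] = (d[:-1] + d[1:]) / (t[2:] - t[:-2])
    ok = in_band & (v >= min_speed)

    # bridge sub-merge_gap interruptions
    edges = np.flatnonzero(np.diff(np.r_[False, ok, False]))
    runs = [(a, b - 1) for a, b in zip(edges[::2], edges[1::2])]
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and t[a] - t[merged[-1][1]] < merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    rows = [
        {"type": "walling", "start": t[a], "end": t[b]}
        for a, b in merged
        if t[b] - t[a] >= min_duration
    ]
    if not rows:
        return _empty_events()
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def detect_stereotypy(traj: pd.DataFrame, arena: RectangularTank,
                      **kwargs) -> pd.DataFrame:
    """Run both detectors on one trajectory and concatenate the events."""
    circles = detect_small_circles(traj, arena=arena,
                                   **{k: v for k, v in kwargs.items()
                                      if k in ("min_total_turn", "max_loop_diameter",
                                               "window", "noise_floor")})
    walls = detect_walling(traj, arena,
                           **{k: v for k, v in kwargs.items()
                              if k in ("band", "min_duration", "min_speed", "merge_gap")})
    out = pd.concat([circles, walls], ignore_index=True)
    return out.sort_values("start", ignore_index=True) if len(out) else out


def summarize_events(events: pd.DataFrame, duration: float) -> dict:
    """Counts per minute and total stereotypy time for one subject.

    ``duration`` is the scored recording length in seconds.
    """
    if duration <= 0:
        raise DataError("summary needs a positive recording duration")
    out = {}
    for kind in ("small_circle", "walling"):
        sel = events[events["type"] == kind] if len(events) else events
        out[f"{kind}_count"] = int(len(sel))
        out[f"{kind}_per_min"] = len(sel) / (duration / 60.0)
        out[f"{kind}_time"] = float((sel["end"] - sel["start"]).sum()) if len(sel) else 0.0
    out["stereotypy_time"] = out["small_circle_time"] + out["walling_time"]
    return out
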