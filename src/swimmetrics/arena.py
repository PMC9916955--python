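"""Arena models and zone assignment.

Three arena geometries cover the assays: a circular well of a 24-well plate
(larval assays), a square open-field tank (adult locomotion/thigmotaxis) and
a three-chamber social-preference tank. All coordinates are arena-local
millimetres with the origin at the arena centre and y increasing upward.

Each arena partitions its area into named zones; zone partitions are exact
covers (every point belongs to exactly one zone). The larval well follows
the equal-area convention: an inner circle of radius R/sqrt(2) splits the
well into ``center`` and ``outer`` regions of identical area. The adult
open-field tank uses a wall band; at the default ``band_fraction`` of
(1 - 1/sqrt(2))/2 ~ 0.1464 the ``peripheral`` band and ``center`` square
also have equal areas, mirroring the larval convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

EQUAL_AREA_BAND_FRACTION = (1.0 - 1.0 / np.sqrt(2.0)) / 2.0  # ~0.146447


def _as_xy(x, y):
    x = np.atleast_1d(np.asarray(x, float))
    y = np.atleast_1d(np.asarray(y, float))
    return x, y


@dataclass(frozen=True)
class CircularWell:
    """Circular well with concentric equal-area (by default) center/outer zones."""

    radius: float
    inner_radius: float | None = None
    kind: str = field(default="circular_well", init=False)

    def __post_init__(self):
        if self.radius <= 0:
            raise ConfigError(f"well radius must be positive, got {self.radius}")
        if self.inner_radius is None:
            object.__setattr__(self, "inner_radius", self.radius / np.sqrt(2.0))
        if not 0 < self.inner_radius < self.radius:
            raise ConfigError("inner radius must lie strictly inside the well")

    @property
    def zones(self) -> tuple[str, ...]:
        return ("center", "outer")

    @property
    def total_area(self) -> float:
        return float(np.pi * self.radius**2)

    def area(self, zone: str) -> float:
        inner = np.pi * self.inner_radius**2
        if zone == "center":
            return float(inner)
        if zone == "outer":
            return float(self.total_area - inner)
        raise ConfigError(f"unknown zone {zone!r}")

    def contains(self, x, y, tol: float = 0.0):
        x, y = _as_xy(x, y)
        return np.hypot(x, y) <= self.radius + tol

    def zone_of(self, x, y):
        x, y = _as_xy(x, y)
        return np.where(np.hypot(x, y) < self.inner_radius, "center", "outer")

    def clamp(self, x, y):
        x, y = _as_xy(x, y)
        r = np.hypot(x, y)
        f = np.where(r > self.radius, self.radius / np.maximum(r, 1e-300), 1.0)
        return x * f, y * f

    def wall_distance(self, x, y):
        x, y = _as_xy(x, y)
        return self.radius - np.hypot(x, y)

    def wall_bearing(self, x, y):
        x, y = _as_xy(x, y)
        return np.arctan2(y, x)

    def reflect(self, x, y):
        """Fold points outside the wall back inside (radial mirror)."""
        x, y = _as_xy(x, y)
        r = np.hypot(x, y)
        r_new = np.where(r > self.radius, 2 * self.radius - r, r)
        r_new = np.clip(r_new, 0.0, self.radius)  # huge steps: clamp at wall
        f = np.where(r > 0, r_new / np.maximum(r, 1e-300), 1.0)
        return x * f, y * f

    def sample_uniform(self, n: int, rng: np.random.Generator):
        r = self.radius * np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * np.pi, n)
        return r * np.cos(th), r * np.sin(th)


@dataclass(frozen=True)
class RectangularTank:
    """Axis-aligned rectangular tank with a peripheral wall band and a center zone."""

    width: float
    height: float
    band_fraction: float = EQUAL_AREA_BAND_FRACTION
    kind: str = field(default="open_tank", init=False)

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ConfigError("tank dimensions must be positive")
        if not 0 < self.band_fraction < 0.5:
            raise ConfigError(
                f"band_fraction must be in (0, 0.5), got {self.band_fraction}"
            )

    @property
    def band(self) -> float:
        """Wall-band thickness in mm."""
        return self.band_fraction * min(self.width, self.height)

    @property
    def zones(self) -> tuple[str, ...]:
        return ("center", "peripheral")

    @property
    def total_area(self) -> float:
        return float(self.width * self.height)

    def area(self, zone: str) -> float:
        cw = self.width - 2 * self.band
        ch = self.height - 2 * self.band
        if zone == "center":
            return float(cw * ch)
        if zone == "peripheral":
            return float(self.total_area - cw * ch)
        raise ConfigError(f"unknown zone {zone!r}")

    def contains(self, x, y, tol: float = 0.0):
        x, y = _as_xy(x, y)
        return (np.abs(x) <= self.width / 2 + tol) & (np.abs(y) <= self.height / 2 + tol)

    def zone_of(self, x, y):
        x, y = _as_xy(x, y)
        inside = (np.abs(x) < self.width / 2 - self.band) & (
            np.abs(y) < self.height / 2 - self.band
        )
        return np.where(inside, "center", "peripheral")

    def clamp(self, x, y):
        x, y = _as_xy(x, y)
        return (
            np.clip(x, -self.width / 2, self.width / 2),
            np.clip(y, -self.height / 2, self.height / 2),
        )

    def wall_distance(self, x, y):
        x, y = _as_xy(x, y)
        return np.minimum(self.width / 2 - np.abs(x), self.height / 2 - np.abs(y))

    def wall_bearing(self, x, y):
        """Bearing toward the nearest wall (axis-aligned)."""
        x, y = _as_xy(x, y)
        dx = self.width / 2 - np.abs(x)
        dy = self.height / 2 - np.abs(y)
        toward_x = dx <= dy
        bx = np.where(x >= 0, 0.0, np.pi)
        by = np.where(y >= 0, np.pi / 2, -np.pi / 2)
        return np.where(toward_x, bx, by)

    def reflect(self, x, y):
        x, y = _as_xy(x, y)
        hw, hh = self.width / 2, self.height / 2
        # mirror about the crossed wall; clamp pathological multi-width steps
        x = np.where(x > hw, 2 * hw - x, x)
        x = np.where(x < -hw, -2 * hw - x, x)
        y = np.where(y > hh, 2 * hh - y, y)
        y = np.where(y < -hh, -2 * hh - y, y)
        return np.clip(x, -hw, hw), np.clip(y, -hh, hh)

    def sample_uniform(self, n: int, rng: np.random.Generator):
        return (
            rng.uniform(-self.width / 2, self.width / 2, n),
            rng.uniform(-self.height / 2, self.height / 2, n),
        )


@dataclass(frozen=True)
class ThreeChamberTank:
    """Three-chamber social tank; the subject swims in the middle chamber only.

    The full tank (``length`` x ``width``) is split along x into three
    chambers by two transparent dividers; stimulus fish occupy the outer
    chambers. Zone assignment partitions the *middle* chamber into a sector
    abutting each divider (depth = ``sector_fraction`` x middle-chamber
    length, up to 0.5) plus a ``neutral`` strip when the sectors do not meet.
    Sector labels default to the social-preference assay
    (``conspecific_sector`` on the stimulus side, ``empty_sector`` opposite);
    the kin assay relabels them ``kin_sector``/``nonkin_sector``.
    """

    length: float = 210.0
    width: float = 110.0
    sector_fraction: float = 0.5
    chamber_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    sector_labels: tuple[str, str] = ("conspecific_sector", "empty_sector")
    kind: str = field(default="three_chamber", init=False)

    def __post_init__(self):
        if self.length <= 0 or self.width <= 0:
            raise ConfigError("tank dimensions must be positive")
        if abs(sum(self.chamber_fractions) - 1.0) > 1e-9:
            raise ConfigError("chamber fractions must sum to 1")
        if not 0 < self.sector_fraction <= 0.5:
            raise ConfigError(
                "sector_fraction must be in (0, 0.5]: sectors may not overlap"
            )

    @property
    def middle_length(self) -> float:
        return self.chamber_fractions[1] * self.length

    @property
    def sector_depth(self) -> float:
        return self.sector_fraction * self.middle_length

    @property
    def zones(self) -> tuple[str, ...]:
        if self.sector_fraction >= 0.5 - 1e-12:
            return self.sector_labels
        return (self.sector_labels[0], "neutral", self.sector_labels[1])

    @property
    def total_area(self) -> float:
        """Area of the subject's (middle-chamber) domain."""
        return float(self.middle_length * self.width)

    def area(self, zone: str) -> float:
        sector = self.sector_depth * self.width
        if zone in self.sector_labels:
            return float(sector)
        if zone == "neutral" and "neutral" in self.zones:
            return float(self.total_area - 2 * sector)
        raise ConfigError(f"unknown zone {zone!r}")

    # middle-chamber extent along x
    @property
    def _hx(self) -> float:
        return self.middle_length / 2

    def contains(self, x, y, tol: float = 0.0):
        x, y = _as_xy(x, y)
        return (np.abs(x) <= self._hx + tol) & (np.abs(y) <= self.width / 2 + tol)

    def zone_of(self, x, y):
        """Stimulus-side sector abuts the *left* divider (negative x)."""
        x, y = _as_xy(x, y)
        left, right = self.sector_labels
        out = np.full(x.shape, "neutral", dtype=object)
        out[x < -self._hx + self.sector_depth] = left
        # at sector_fraction = 0.5 the sectors meet at x = 0 and "neutral" vanishes
        out[x >= self._hx - self.sector_depth] = right
        return out.astype(str)

    def clamp(self, x, y):
        x, y = _as_xy(x, y)
        return (
            np.clip(x, -self._hx, self._hx),
            np.clip(y, -self.width / 2, self.width / 2),
        )

    def wall_distance(self, x, y):
        x, y = _as_xy(x, y)
        return np.minimum(self._hx - np.abs(x), self.width / 2 - np.abs(y))

    def wall_bearing(self, x, y):
        x, y = _as_xy(x, y)
        dx = self._hx - np.abs(x)
        dy = self.width / 2 - np.abs(y)
        bx = np.where(x >= 0, 0.0, np.pi)
        by = np.where(y >= 0, np.pi / 2, -np.pi / 2)
        return np.where(dx <= dy, bx, by)

    def reflect(self, x, y):
        x, y = _as_xy(x, y)
        hx, hy = self._hx, self.width / 2
        x = np.where(x > hx, 2 * hx - x, x)
        x = np.where(x < -hx, -2 * hx - x, x)
        y = np.where(y > hy, 2 * hy - y, y)
        y = np.where(y < -hy, -2 * hy - y, y)
        return np.clip(x, -hx, hx), np.clip(y, -hy, hy)

    def sample_uniform(self, n: int, rng: np.random.Generator):
        return (
            rng.uniform(-self._hx, self._hx, n),
            rng.uniform(-self.width / 2, self.width / 2, n),
        )

    @property
    def stimulus_bearing(self) -> float:
        """Heading (radians) pointing toward the stimulus-side divider."""
        return float(np.pi)


Arena = CircularWell | RectangularTank | ThreeChamberTank


# ---------------------------------------------------------------------------
# factory functions


def make_equal_area_well(radius: float) -> CircularWell:
    """Circular well split into inner/outer regions of equal area (inner R/sqrt(2))."""
    return CircularWell(radius=radius)


def make_peripheral_band(width: float, height: float,
                         band_fraction: float = EQUAL_AREA_BAND_FRACTION) -> RectangularTank:
    """Open tank with a wall band; default band makes peripheral/center areas equal."""
    return RectangularTank(width=width, height=height, band_fraction=band_fraction)


def make_three_chamber(length: float = 210.0, width: float = 110.0,
                       sector_fraction: float = 0.5,
                       sector_labels: tuple[str, str] = ("conspecific_sector", "empty_sector"),
                       ) -> ThreeChamberTank:
    """Three-chamber tank; dividers at thirds by default, sectors abutting them."""
    return ThreeChamberTank(
        length=length, width=width, sector_fraction=sector_fraction,
        sector_labels=sector_labels,
    )


# ---------------------------------------------------------------------------
# zone assignment


@dataclass
class ZoneAssignment:
    """Per-sample zone labels and per-zone accumulators for one trajectory.

    Each inter-sample interval (duration and step distance) is attributed to
    the zone of the interval's *start* sample, so per-zone times sum exactly
    to the observed duration and per-zone distances to the total path length.
    """

    samples: pd.DataFrame  # t, x, y, zone, step_dt, step_dist
    arena: Arena

    def totals(self, t_start: float | None = None, t_stop: float | None = None) -> pd.DataFrame:
        """Per-zone time (s) and distance (mm), restricted to intervals whose
        start sample falls in ``[t_start, t_stop)``."""
        df = self.samples
        if t_start is not None:
            df = df[df["t"] >= t_start]
        if t_stop is not None:
            df = df[df["t"] < t_stop]
        agg = df.groupby("zone", sort=False)[["step_dt", "step_dist"]].sum()
        out = pd.DataFrame(
            {"time": 0.0, "distance": 0.0}, index=pd.Index(self.arena.zones, name="zone")
        )
        out.loc[agg.index, "time"] = agg["step_dt"].to_numpy()
        out.loc[agg.index, "distance"] = agg["step_dist"].to_numpy()
        return out

    def time_in(self, zone: str, t_start=None, t_stop=None) -> float:
        return float(self.totals(t_start, t_stop).loc[zone, "time"])

    def distance_in(self, zone: str, t_start=None, t_stop=None) -> float:
        return float(self.totals(t_start, t_stop).loc[zone, "distance"])

    def total_time(self, t_start=None, t_stop=None) -> float:
        return float(self.totals(t_start, t_stop)["time"].sum())

    def total_distance(self, t_start=None, t_stop=None) -> float:
        return float(self.totals(t_start, t_stop)["distance"].sum())


def assign_zones(traj: pd.DataFrame, arena: Arena, tolerance: float = 0.5) -> ZoneAssignment:
    """Assign every trajectory sample and step to an arena zone.

    Points outside the arena by at most ``tolerance`` mm (tracker jitter)
    are clamped to the boundary; points further out raise :class:`DataError`
    naming the first offending sample. Steps crossing a zone boundary are
    attributed wholly to the zone of the step's start point.
    """
    t = traj["t"].to_numpy(float)
    x = traj["x"].to_numpy(float)
    y = traj["y"].to_numpy(float)
    inside = arena.contains(x, y, tol=tolerance)
    if not np.all(inside):
        i = int(np.argmax(~inside))
        raise DataError(
            f"sample {i} (t={t[i]:g}, x={x[i]:g}, y={y[i]:g}) lies outside the "
            f"arena by more than {tolerance} mm"
        )
    x, y = arena.clamp(x, y)
    zone = arena.zone_of(x, y)

    n = len(t)
    step_dt = np.zeros(n)
    step_dist = np.zeros(n)
    if n >= 2:
        step_dt[:-1] = np.diff(t)
        step_dist[:-1] = np.hypot(np.diff(x), np.diff(y))
        if "segment" in traj.columns:
            seg = traj["segment"].to_numpy()
            last_of_segment = np.r_[seg[:-1] != seg[1:], True]
            step_dt[last_of_segment] = 0.0
            step_dist[last_of_segment] = 0.0
    samples = pd.DataFrame(
        {"t": t, "x": x, "y": y, "zone": zone, "step_dt": step_dt, "step_dist": step_dist}
    )
    return ZoneAssignment(samples=samples, arena=arena)
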