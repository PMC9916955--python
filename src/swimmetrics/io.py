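"""Reading, writing and validation of tracking exports.

Two delimited-text dialects are supported, emulating the per-subject exports
of commercial video trackers (Zebrabox/Zebralab-style):

* ``trajectory`` — one row per video frame: ``subject_id, t, x, y`` with time
  in seconds and positions in millimetres in an arena-local frame (origin at
  the arena centre, y increasing upward).
* ``binned`` — one row per time bin: ``subject_id, t_start, dt, distance``
  plus an optional dimensionless ``activity`` count column.

Files are self-describing: metadata lines prefixed ``#`` declare the format,
the units and the subject roster (id, genotype, treatment, arena), so a file
round-trips through :func:`write_tracking` / :func:`read_tracking` without
side-band information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, ParseError

log = logging.getLogger(__name__)

MAGIC = "swimmetrics-tracking v1"

TRACK_COLUMNS = ["subject_id", "t", "x", "y"]
BIN_COLUMNS = ["subject_id", "t_start", "dt", "distance"]

#: multiplicative factors to the canonical units (mm, s)
_LENGTH_UNITS = {"mm": 1.0, "cm": 10.0, "m": 1000.0}
_TIME_UNITS = {"s": 1.0, "ms": 1e-3, "min": 60.0}

DEFAULT_GENOTYPES = ("WT", "mutant", "het")


@dataclass
class Dataset:
    """A cohort of tracked subjects plus their trajectories and/or binned series.

    Attributes
    ----------
    subjects
        One row per subject: ``subject_id, genotype, treatment, arena_id``.
    tracks
        Frame-level positions (``subject_id, t, x, y``) or ``None``.
    bins
        Binned activity (``subject_id, t_start, dt, distance[, activity]``)
        or ``None``.
    metadata
        Free-form mapping; recognised keys include ``sampling_rate_hz``,
        ``genotypes`` (allowed genotype vocabulary) and ``seed``.
    """

    subjects: pd.DataFrame
    tracks: pd.DataFrame | None = None
    bins: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def track_for(self, subject_id: str) -> pd.DataFrame:
        if self.tracks is None:
            raise DataError("dataset has no trajectory data")
        out = self.tracks[self.tracks["subject_id"] == subject_id]
        if out.empty:
            raise DataError(f"no trajectory for subject {subject_id!r}")
        return out.reset_index(drop=True)

    def bins_for(self, subject_id: str) -> pd.DataFrame:
        if self.bins is None:
            raise DataError("dataset has no binned data")
        out = self.bins[self.bins["subject_id"] == subject_id]
        if out.empty:
            raise DataError(f"no bins for subject {subject_id!r}")
        return out.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects["subject_id"])

    def validate(self) -> "Dataset":
        _validate_subjects(self.subjects, self.metadata)
        if self.tracks is not None:
            ids = set(self.subjects["subject_id"])
            missing = set(self.tracks["subject_id"]) - ids
            if missing:
                raise DataError(f"track records for undeclared subjects: {sorted(missing)}")
            for sid, grp in self.tracks.groupby("subject_id", sort=False):
                validate_trajectory(grp, subject_id=str(sid))
        if self.bins is not None:
            ids = set(self.subjects["subject_id"])
            missing = set(self.bins["subject_id"]) - ids
            if missing:
                raise DataError(f"bin records for undeclared subjects: {sorted(missing)}")
            for sid, grp in self.bins.groupby("subject_id", sort=False):
                validate_bins(grp, subject_id=str(sid))
        return self


def _validate_subjects(subjects: pd.DataFrame, metadata: dict) -> None:
    required = {"subject_id", "genotype", "treatment", "arena_id"}
    missing = required - set(subjects.columns)
    if missing:
        raise DataError(f"subject table missing columns: {sorted(missing)}")
    if subjects["subject_id"].duplicated().any():
        dup = subjects.loc[subjects["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise DataError(f"duplicate subject id {dup!r}")
    vocab = set(metadata.get("genotypes", DEFAULT_GENOTYPES))
    bad = set(subjects["genotype"]) - vocab
    if bad:
        raise DataError(f"genotype labels outside declared vocabulary {sorted(vocab)}: {sorted(bad)}")


def validate_trajectory(traj: pd.DataFrame, subject_id: str = "?",
                        period_rtol: float = 1e-3) -> None:
    """Check one subject's trajectory invariants.

    Time must be strictly increasing, coordinates finite, and the sampling
    period constant up to ``period_rtol`` (gaps that are near-integer
    multiples of the base period are tolerated; see :func:`fill_gaps`).
    """
    t = traj["t"].to_numpy(float)
    if len(t) == 0:
        return
    if not np.all(np.isfinite(traj[["t", "x", "y"]].to_numpy(float))):
        raise DataError(f"subject {subject_id}: non-finite coordinate or time")
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise DataError(
            f"subject {subject_id}: time not strictly increasing at t={t[i + 1]!r}"
        )
    if len(dt) > 1:
        period = np.min(dt)
        # every interval must be close to an integer number of base periods
        k = np.round(dt / period)
        if np.any(np.abs(dt - k * period) > period_rtol * period * np.maximum(k, 1)):
            i = int(np.argmax(np.abs(dt - k * period) > period_rtol * period * np.maximum(k, 1)))
            raise DataError(
                f"subject {subject_id}: irregular sampling period at t={t[i]:g} "
                f"(dt={dt[i]:g}, base period {period:g})"
            )


def validate_bins(bins: pd.DataFrame, subject_id: str = "?", rtol: float = 1e-6) -> None:
    """Check one subject's bin invariants: contiguous, non-overlapping, uniform dt."""
    t0 = bins["t_start"].to_numpy(float)
    dt = bins["dt"].to_numpy(float)
    if len(t0) == 0:
        return
    if np.any(dt <= 0):
        raise DataError(f"subject {subject_id}: non-positive bin duration")
    if np.any(np.abs(dt - dt[0]) > rtol * dt[0]):
        raise DataError(f"subject {subject_id}: bin duration not uniform")
    gaps = np.diff(t0) - dt[:-1]
    if np.any(np.abs(gaps) > rtol * dt[0]):
        raise DataError(f"subject {subject_id}: bins not contiguous/non-overlapping")
    if np.any(bins["distance"].to_numpy(float) < 0):
        raise DataError(f"subject {subject_id}: negative bin distance")


# ---------------------------------------------------------------------------
# reading


def _parse_header(lines: list[str]) -> tuple[dict, list[dict], int]:
    """Parse leading ``#`` metadata lines; return (metadata, subjects, n_header_lines)."""
    meta: dict = {}
    subjects: list[dict] = []
    n = 0
    for i, raw in enumerate(lines):
        line = raw.strip()
        if not line.startswith("#"):
            break
        n = i + 1
        body = line.lstrip("#").strip()
        if not body:
            continue
        if body == MAGIC:
            continue
        if ":" not in body:
            raise ParseError(f"malformed metadata line {body!r}", line=i + 1)
        key, _, value = body.partition(":")
        key = key.strip()
        value = value.strip()
        if key == "subject":
            rec: dict = {}
            for tok in value.split():
                if "=" not in tok:
                    raise ParseError(f"malformed subject token {tok!r}", line=i + 1)
                k, _, v = tok.partition("=")
                rec[k] = v
            if "id" not in rec:
                raise ParseError("subject line lacks id=", line=i + 1)
            subjects.append(
                {
                    "subject_id": rec["id"],
                    "genotype": rec.get("genotype", "WT"),
                    "treatment": rec.get("treatment", "none"),
                    "arena_id": rec.get("arena", "arena"),
                }
            )
        else:
            meta[key] = value
    return meta, subjects, n


def _unit_factors(meta: dict) -> tuple[float, float]:
    units = meta.get("units", "mm,s")
    try:
        lu, tu = [u.strip() for u in units.split(",")]
    except ValueError as exc:
        raise ConfigError(f"units declaration {units!r} must be '<length>,<time>'") from exc
    if lu not in _LENGTH_UNITS:
        raise ConfigError(f"unknown length unit {lu!r} (known: {sorted(_LENGTH_UNITS)})")
    if tu not in _TIME_UNITS:
        raise ConfigError(f"unknown time unit {tu!r} (known: {sorted(_TIME_UNITS)})")
    return _LENGTH_UNITS[lu], _TIME_UNITS[tu]


def read_tracking(path: str | Path, format: str | None = None) -> Dataset:
    """Read a tracking export into a validated :class:`Dataset`.

    Parameters
    ----------
    path
        CSV file with ``#`` metadata header lines (see module docstring).
    format
        ``"trajectory"`` or ``"binned"``; ``None`` takes the format declared
        in the file header.

    Raises
    ------
    ParseError
        Malformed row or header, naming the 1-based line.
    DataError
        Invariant violation (e.g. duplicated timestamp).
    ConfigError
        Unknown unit or undeclared format.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"tracking file not found: {path}")
    lines = path.read_text().splitlines()
    meta, subject_rows, n_header = _parse_header(lines)

    fmt = format or meta.get("format")
    if fmt not in ("trajectory", "binned"):
        raise ConfigError(f"tracking format must be 'trajectory' or 'binned', got {fmt!r}")
    lf, tf = _unit_factors(meta)

    expected = TRACK_COLUMNS if fmt == "trajectory" else BIN_COLUMNS
    body = lines[n_header:]
    if not body:
        raise ParseError("file has no column header row", line=n_header)
    header = [c.strip() for c in body[0].split(",")]
    missing = [c for c in expected if c not in header]
    if missing:
        raise ParseError(f"missing columns {missing} in header {header}", line=n_header + 1)

    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"could not parse CSV body: {exc}") from exc
    # locate non-numeric rows explicitly so the error names a line
    for col in expected[1:]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"non-numeric value {df[col].iloc[i]!r} in column {col!r}",
                line=n_header + 2 + i,
            )
        df[col] = coerced
    df["subject_id"] = df["subject_id"].astype(str)

    if fmt == "trajectory":
        df["t"] = df["t"] * tf
        df[["x", "y"]] = df[["x", "y"]] * lf
        df = df[TRACK_COLUMNS]
    else:
        df["t_start"] = df["t_start"] * tf
        df["dt"] = df["dt"] * tf
        df["distance"] = df["distance"] * lf
        cols = BIN_COLUMNS + (["activity"] if "activity" in df.columns else [])
        df = df[cols]
    meta["units"] = "mm,s"

    if not subject_rows:
        subject_rows = [
            {"subject_id": sid, "genotype": "WT", "treatment": "none", "arena_id": "arena"}
            for sid in df["subject_id"].unique()
        ]
    subjects = pd.DataFrame(subject_rows)

    # keys that look numeric become numeric metadata
    for key in ("sampling_rate_hz", "seed"):
        if key in meta:
            meta[key] = float(meta[key]) if "." in str(meta[key]) else int(float(meta[key]))

    ds = Dataset(
        subjects=subjects,
        tracks=df if fmt == "trajectory" else None,
        bins=df if fmt == "binned" else None,
        metadata=meta,
    )
    return ds.validate()


def write_tracking(dataset: Dataset, path: str | Path, format: str = "trajectory",
                   float_format: str | None = None) -> Path:
    # float_format=None keeps pandas' shortest round-tripping repr, so
    # write -> read is the identity on the numeric columns
    """Write a Dataset to the self-describing CSV dialect. Returns the path."""
    path = Path(path)
    if format == "trajectory":
        if dataset.tracks is None:
            raise DataError("dataset has no trajectory data to write")
        df, cols = dataset.tracks, TRACK_COLUMNS
    elif format == "binned":
        if dataset.bins is None:
            raise DataError("dataset has no binned data to write")
        cols = BIN_COLUMNS + (["activity"] if "activity" in dataset.bins.columns else [])
        df = dataset.bins
    else:
        raise ConfigError(f"unknown tracking format {format!r}")

    with open(path, "w") as fh:
        fh.write(f"# {MAGIC}\n")
        fh.write(f"# format: {format}\n")
        fh.write("# units: mm,s\n")
        for key, value in dataset.metadata.items():
            if key in ("units", "format"):
                continue
            fh.write(f"# {key}: {value}\n")
        for _, row in dataset.subjects.iterrows():
            fh.write(
                f"# subject: id={row['subject_id']} genotype={row['genotype']} "
                f"treatment={row['treatment']} arena={row['arena_id']}\n"
            )
        df[cols].to_csv(fh, index=False, float_format=float_format)
    return path


# ---------------------------------------------------------------------------
# trajectory post-processing


def fill_gaps(traj: pd.DataFrame, max_gap: float = 0.2) -> pd.DataFrame:
    """Linearly interpolate tracker dropouts up to ``max_gap`` seconds.

    Gaps longer than ``max_gap`` are left in place but start a new segment
    (integer ``segment`` column) and are logged; downstream step-based
    computations must not bridge segment boundaries.
    """
    t = traj["t"].to_numpy(float)
    if len(t) < 2:
        out = traj.copy()
        out["segment"] = 0
        return out
    dt = np.diff(t)
    period = float(np.min(dt))
    rows = [traj.iloc[[0]].assign(segment=0)]
    segment = 0
    x = traj["x"].to_numpy(float)
    y = traj["y"].to_numpy(float)
    sid = traj["subject_id"].iloc[0]
    for i in range(1, len(t)):
        gap = t[i] - t[i - 1]
        if gap > 1.5 * period and gap <= max_gap:
            n_insert = int(round(gap / period)) - 1
            ts = t[i - 1] + period * np.arange(1, n_insert + 1)
            frac = (ts - t[i - 1]) / gap
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "t": ts,
                        "x": x[i - 1] + frac * (x[i] - x[i - 1]),
                        "y": y[i - 1] + frac * (y[i] - y[i - 1]),
                        "segment": segment,
                    }
                )
            )
        elif gap > max_gap:
            segment += 1
            log.warning(
                "subject %s: %.3f s gap at t=%.3f exceeds max_gap=%.3f; starting segment %d",
                sid, gap, t[i - 1], max_gap, segment,
            )
        rows.append(traj.iloc[[i]].assign(segment=segment))
    return pd.concat(rows, ignore_index=True)


def step_lengths(traj: pd.DataFrame) -> np.ndarray:
    """Euclidean length of each step; length n-1 for n samples."""
    xy = traj[["x", "y"]].to_numpy(float)
    return np.hypot(*np.diff(xy, axis=0).T)


def path_length(traj: pd.DataFrame) -> float:
    """Total Euclidean path length of a trajectory in mm."""
    return float(step_lengths(traj).sum())


def bin_activity(traj: pd.DataFrame, dt: float) -> pd.DataFrame:
    """Bin one subject's trajectory into fixed time windows.

    Each step's full length is attributed to the half-open bin
    ``[t_start, t_start + dt)`` containing the step's *start* time, so the
    total distance is conserved exactly for any ``dt``.

    Parameters
    ----------
    traj
        One subject's trajectory (``subject_id, t, x, y``).
    dt
        Bin width in seconds; must be positive and at least the sampling
        period.

    Returns
    -------
    DataFrame with columns ``subject_id, t_start, dt, distance``; bins cover
    ``[t0, t0 + n*dt)`` where ``t0`` is the first sample time. Empty input
    yields an empty frame.
    """
    if dt <= 0:
        raise ConfigError(f"bin width must be positive, got {dt}")
    if len(traj) == 0:
        return pd.DataFrame(columns=BIN_COLUMNS)
    t = traj["t"].to_numpy(float)
    if len(t) >= 2:
        period = float(np.min(np.diff(t)))
        if period > dt * (1 + 1e-9):
            raise ConfigError(
                f"bin width {dt} s is finer than the sampling period {period:g} s"
            )
    sid = traj["subject_id"].iloc[0]
    steps = step_lengths(traj)
    t0 = t[0]
    if len(steps) == 0:
        return pd.DataFrame(
            {"subject_id": [sid], "t_start": [t0], "dt": [dt], "distance": [0.0]}
        )
    # bin index of each step's start time; guard the last edge against fp round-up
    idx = np.floor((t[:-1] - t0) / dt).astype(int)
    span = t[-1] - t0
    n_bins = max(int(np.floor(span / dt)) + 1, idx.max() + 1)
    dist = np.bincount(idx, weights=steps, minlength=n_bins)
    return pd.DataFrame(
        {
            "subject_id": sid,
            "t_start": t0 + dt * np.arange(n_bins),
            "dt": dt,
            "distance": dist,
        }
    )


def bin_dataset(dataset: Dataset, dt: float = 1.0) -> Dataset:
    """Derive a binned Dataset from a trajectory Dataset (per-subject bins)."""
    if dataset.tracks is None:
        raise DataError("dataset has no trajectory data to bin")
    parts = [
        bin_activity(grp.reset_index(drop=True), dt)
        for _, grp in dataset.tracks.groupby("subject_id", sort=False)
    ]
    bins = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=BIN_COLUMNS)
    return Dataset(
        subjects=dataset.subjects.copy(),
        tracks=dataset.tracks,
        bins=bins,
        metadata=dict(dataset.metadata),
    )
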