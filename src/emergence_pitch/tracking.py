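"""Tracking-data model, readers/writers, and preprocessing.

Positions live in pitch-centred coordinates: the origin is the centre spot,
x runs along the long axis of a 105 x 68 m pitch (both dimensions
configurable), units are metres.  Each team contributes exactly ten outfield
players per frame; goalkeepers are excluded upstream.  Velocities, when
present, are first differences of position scaled by the sampling rate and
are never computed across a half-time gap.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TEAMS = ("home", "away")

#: events understood by the pipeline
EVENT_TYPES = (
    "half_start",
    "half_end",
    "shot",
    "possession_gain",
    "red_card",
    "substitution",
)


class TrackingError(ValueError):
    """Base class for tracking-data failures."""


class ParseError(TrackingError):
    """A tracking/event file could not be parsed."""


class ValidationError(TrackingError):
    """Parsed data violate a structural invariant."""


# ---------------------------------------------------------------------------
# MatchTracking
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MatchTracking:
    """Per-frame player positions (and optional velocities) for both teams.

    Attributes
    ----------
    times : ndarray, shape (T,)
        Frame timestamps in seconds, strictly increasing, uniformly spaced
        at ``1/sample_rate_hz`` within each half.
    positions : dict[str, ndarray]
        ``team -> (T, N, 2)`` array of x/y positions in metres.
    velocities : dict[str, ndarray] or None
        ``team -> (T, N, 2)`` array of vx/vy in m/s, or None when velocities
        have not been computed (e.g. right after downsampling).
    vel_valid : ndarray or None, shape (T,)
        False on frames whose velocity is a placeholder (the first frame of
        each half); None iff ``velocities`` is None.
    half_bounds : list of (start, end)
        Inclusive time bounds of each half.
    margin : float
        Allowed out-of-pitch excursion in metres for validation.
    """

    times: np.ndarray
    positions: dict[str, np.ndarray]
    velocities: dict[str, np.ndarray] | None = None
    vel_valid: np.ndarray | None = None
    pitch_length: float = 105.0
    pitch_width: float = 68.0
    sample_rate_hz: float = 1.0
    half_bounds: list[tuple[float, float]] | None = None
    margin: float = 5.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = {k: np.asarray(v, dtype=float) for k, v in self.positions.items()}
        if self.velocities is not None:
            self.velocities = {k: np.asarray(v, dtype=float) for k, v in self.velocities.items()}
            if self.vel_valid is None:
                self.vel_valid = np.ones(len(self.times), dtype=bool)
            else:
                self.vel_valid = np.asarray(self.vel_valid, dtype=bool)
        if self.half_bounds is None:
            if len(self.times) == 0:
                raise ValidationError("MatchTracking requires at least one frame")
            self.half_bounds = _infer_half_bounds(self.times, self.sample_rate_hz)
        self.half_bounds = [(float(s), float(e)) for s, e in self.half_bounds]

    # -- basic introspection -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_players(self) -> int:
        return next(iter(self.positions.values())).shape[1]

    @property
    def teams(self) -> tuple[str, ...]:
        return tuple(self.positions.keys())

    def half_mask(self, bounds: tuple[float, float]) -> np.ndarray:
        s, e = bounds
        return (self.times >= s - 1e-9) & (self.times <= e + 1e-9)

    def half_index(self, t: float) -> int:
        """Index of the half containing time ``t`` (raises if in no half)."""
        for h, (s, e) in enumerate(self.half_bounds):
            if s - 1e-9 <= t <= e + 1e-9:
                return h
        raise ValidationError(f"time {t} falls outside every half")

    def subset(self, mask: np.ndarray, half_bounds: list[tuple[float, float]] | None = None) -> "MatchTracking":
        """New MatchTracking restricted to frames where ``mask`` is True."""
        vel = None
        vvalid = None
        if self.velocities is not None:
            vel = {k: v[mask] for k, v in self.velocities.items()}
            vvalid = self.vel_valid[mask]
        return MatchTracking(
            times=self.times[mask],
            positions={k: v[mask] for k, v in self.positions.items()},
            velocities=vel,
            vel_valid=vvalid,
            pitch_length=self.pitch_length,
            pitch_width=self.pitch_width,
            sample_rate_hz=self.sample_rate_hz,
            half_bounds=half_bounds,
            margin=self.margin,
        )

    # -- validation ----------------------------------------------------------

    def validate(self) -> "MatchTracking":
        """Check all structural invariants; return self for chaining."""
        if self.n_frames == 0:
            raise ValidationError("no frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times are not strictly increasing")
        dt = 1.0 / self.sample_rate_hz
        for s, e in self.half_bounds:
            tt = self.times[self.half_mask((s, e))]
            if len(tt) > 1 and not np.allclose(np.diff(tt), dt, atol=1e-6):
                raise ValidationError(f"non-uniform spacing inside half [{s}, {e}]")
        for team, pos in self.positions.items():
            if pos.shape != (self.n_frames, self.n_players, 2):
                raise ValidationError(f"positions[{team}] has shape {pos.shape}")
            if not np.all(np.isfinite(pos)):
                raise ValidationError(f"non-finite position for team {team}")
            if np.any(np.abs(pos[..., 0]) > self.pitch_length / 2 + self.margin) or np.any(
                np.abs(pos[..., 1]) > self.pitch_width / 2 + self.margin
            ):
                raise ValidationError(f"player off pitch (margin {self.margin} m) for team {team}")
        if self.velocities is not None:
            self._check_velocity_consistency()
        return self

    def _check_velocity_consistency(self) -> None:
        dt = 1.0 / self.sample_rate_hz
        for team, vel in self.velocities.items():
            pos = self.positions[team]
            consecutive = np.isclose(np.diff(self.times), dt, atol=1e-6)
            check = self.vel_valid[1:] & consecutive
            expect = (pos[1:] - pos[:-1]) * self.sample_rate_hz
            if not np.allclose(vel[1:][check], expect[check], atol=1e-9):
                raise ValidationError(f"velocity inconsistent with positions for team {team}")


def _infer_half_bounds(times: np.ndarray, rate_hz: float) -> list[tuple[float, float]]:
    """Split the time axis into halves at gaps larger than 1.5 sample steps."""
    if len(times) == 1:
        return [(float(times[0]), float(times[0]))]
    gaps = np.where(np.diff(times) > 1.5 / rate_hz)[0]
    starts = np.concatenate([[0], gaps + 1])
    ends = np.concatenate([gaps, [len(times) - 1]])
    return [(float(times[s]), float(times[e])) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# CSV I/O  (dialect: t,team,player,x,y[,vx,vy])
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("t", "team", "player", "x", "y")


def load_tracking(
    path,
    *,
    pitch_length: float = 105.0,
    pitch_width: float = 68.0,
    sample_rate_hz: float | None = None,
    half_bounds: list[tuple[float, float]] | None = None,
    margin: float = 5.0,
) -> MatchTracking:
    """Read a tracking CSV (``t,team,player,x,y[,vx,vy]``) into a MatchTracking.

    The sampling rate is inferred from the median frame spacing when not
    given; half bounds are inferred from gaps in the time axis when not given.
    Missing velocity columns are tolerated (velocities stay None and can be
    recomputed with :func:`differentiate_positions`).
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot parse tracking file {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    has_vel = "vx" in df.columns and "vy" in df.columns
    numeric_cols = ["t", "player", "x", "y"] + (["vx", "vy"] if has_vel else [])
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            line = int(coerced.index[coerced.isna()][0]) + 2  # header + 1-based
            raise ParseError(f"{path}: malformed value in column '{col}' at line {line}")
        df[col] = coerced

    df = df.sort_values(["t", "team", "player"], kind="stable").reset_index(drop=True)
    times = np.sort(df["t"].unique())
    teams = tuple(sorted(df["team"].unique(), key=lambda x: (x != "home", x)))
    n_per = {
        team: df[df["team"] == team].groupby("t")["player"].nunique() for team in teams
    }
    counts = {c for s in n_per.values() for c in s.unique()}
    if len(counts) != 1:
        for team, s in n_per.items():
            bad = s[s != s.iloc[0]]
            if len(bad):
                raise ValidationError(
                    f"{path}: team {team} has {bad.iloc[0]} players at frame t={bad.index[0]}"
                )
        raise ValidationError(f"{path}: inconsistent player counts {sorted(counts)}")
    n_players = counts.pop()
    expected_rows = len(times) * len(teams) * n_players
    if len(df) != expected_rows:
        raise ValidationError(f"{path}: expected {expected_rows} rows, found {len(df)}")

    positions: dict[str, np.ndarray] = {}
    velocities: dict[str, np.ndarray] | None = {} if has_vel else None
    for team in teams:
        sub = df[df["team"] == team]
        sizes = sub.groupby("t")["player"].size()
        if (sizes != n_players).any():
            t_bad = sizes.index[sizes != n_players][0]
            raise ValidationError(
                f"{path}: team {team} has {sizes[t_bad]} players at frame t={t_bad} (expected {n_players})"
            )
        positions[team] = sub[["x", "y"]].to_numpy().reshape(len(times), n_players, 2)
        if has_vel:
            velocities[team] = sub[["vx", "vy"]].to_numpy().reshape(len(times), n_players, 2)

    if sample_rate_hz is None:
        if len(times) > 1:
            sample_rate_hz = float(np.round(1.0 / np.median(np.diff(times)), 6))
        else:
            sample_rate_hz = 1.0

    tracking = MatchTracking(
        times=times,
        positions=positions,
        velocities=velocities,
        vel_valid=None,
        pitch_length=pitch_length,
        pitch_width=pitch_width,
        sample_rate_hz=sample_rate_hz,
        half_bounds=half_bounds,
        margin=margin,
    )
    if tracking.velocities is not None:
        # first frame of each half carries a placeholder velocity
        vv = np.ones(tracking.n_frames, dtype=bool)
        for s, _ in tracking.half_bounds:
            vv[np.argmin(np.abs(tracking.times - s))] = False
        tracking.vel_valid = vv
    return tracking.validate()


def write_tracking(tracking: MatchTracking, path) -> None:
    """Write a MatchTracking to CSV in the ``t,team,player,x,y[,vx,vy]`` dialect.

    Floats are written in shortest round-trip representation, so
    ``load_tracking(write_tracking(x))`` reproduces all float fields exactly.
    """
    if tracking.n_frames == 0:
        raise TrackingError("refusing to write a MatchTracking with no frames")
    frames = []
    for team in tracking.teams:
        pos = tracking.positions[team]
        T, N, _ = pos.shape
        rec = {
            "t": np.repeat(tracking.times, N),
            "team": team,
            "player": np.tile(np.arange(1, N + 1), T),
            "x": pos[..., 0].ravel(),
            "y": pos[..., 1].ravel(),
        }
        if tracking.velocities is not None:
            vel = tracking.velocities[team]
            rec["vx"] = vel[..., 0].ravel()
            rec["vy"] = vel[..., 1].ravel()
        frames.append(pd.DataFrame(rec))
    out = pd.concat(frames).sort_values(["t", "team", "player"], kind="stable")
    # shortest round-trip float repr so load(write(x)) is bit-exact
    out.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def downsample(tracking: MatchTracking, target_hz: float) -> MatchTracking:
    """Decimate to ``target_hz``, keeping every k-th frame from each half's start.

    Velocities are invalidated (set to None): they are defined on the
    decimated series and must be recomputed with
    :func:`differentiate_positions`.
    """
    ratio = tracking.sample_rate_hz / target_hz
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise TrackingError(
            f"sample rate {tracking.sample_rate_hz} Hz not divisible by target {target_hz} Hz"
        )
    keep = np.zeros(tracking.n_frames, dtype=bool)
    for bounds in tracking.half_bounds:
        idx = np.where(tracking.half_mask(bounds))[0]
        keep[idx[::k]] = True
    out = tracking.subset(keep, half_bounds=None)
    out.velocities = None
    out.vel_valid = None
    out.sample_rate_hz = target_hz
    out.half_bounds = _infer_half_bounds(out.times, target_hz)
    return out


def differentiate_positions(tracking: MatchTracking) -> MatchTracking:
    """Finite-difference velocities: v(t) = (x(t) - x(t-1)) * sample_rate_hz.

    Differencing never crosses a half boundary; the first frame of each half
    gets velocity (0, 0) and is flagged invalid in ``vel_valid``.
    """
    velocities: dict[str, np.ndarray] = {}
    vel_valid = np.zeros(tracking.n_frames, dtype=bool)
    for team, pos in tracking.positions.items():
        vel = np.zeros_like(pos)
        for bounds in tracking.half_bounds:
            idx = np.where(tracking.half_mask(bounds))[0]
            if len(idx) < 2:
                raise TrackingError(
                    f"half {bounds} has {len(idx)} frame(s); need at least 2 to differentiate"
                )
            p = pos[idx]
            vel[idx[1:]] = (p[1:] - p[:-1]) * tracking.sample_rate_hz
            vel_valid[idx[1:]] = True
            vel_valid[idx[0]] = False
        velocities[team] = vel
    out = tracking.subset(np.ones(tracking.n_frames, dtype=bool), half_bounds=tracking.half_bounds)
    out.velocities = velocities
    out.vel_valid = vel_valid
    return out


def segment_halves(tracking: MatchTracking, events: "EventLog") -> list[MatchTracking]:
    """One MatchTracking per half defined by the event log; other frames dropped."""
    bounds = events.half_bounds()
    if not bounds:
        raise TrackingError("event log defines no halves")
    out = []
    for s, e in bounds:
        mask = tracking.half_mask((s, e))
        if not mask.any():
            raise TrackingError(f"no frames inside half [{s}, {e}]")
        out.append(tracking.subset(mask, half_bounds=[(s, e)]))
    return out


def apply_exclusions(tracking: MatchTracking, events: "EventLog") -> MatchTracking:
    """Drop all frames from each red-card event to the end of its half."""
    red = events.events[events.events["event_type"] == "red_card"]
    if red.empty:
        return tracking
    keep = np.ones(tracking.n_frames, dtype=bool)
    new_bounds = list(tracking.half_bounds)
    for t_rc in red["t"]:
        h = tracking.half_index(float(t_rc))
        s, e = tracking.half_bounds[h]
        keep &= ~((tracking.times >= float(t_rc) - 1e-9) & (tracking.times <= e + 1e-9))
        new_bounds[h] = (s, float(t_rc) - 1.0 / tracking.sample_rate_hz)
    new_bounds = [(s, e) for s, e in new_bounds if e >= s]
    return tracking.subset(keep, half_bounds=new_bounds)


# ---------------------------------------------------------------------------
# EventLog
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class EventLog:
    """Timestamped match events plus an optional per-second possession series.

    ``events`` is a DataFrame with columns ``t`` (seconds), ``team``
    (``home``/``away``, empty string for neutral events such as half markers)
    and ``event_type``.  When ``possession_times``/``possession_team`` are not
    supplied, the per-second possession label is derived from
    ``possession_gain`` events: a team holds the ball from its gain until the
    next gain or the end of the half.
    """

    events: pd.DataFrame
    possession_times: np.ndarray | None = None
    possession_team: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.events = self.events.reset_index(drop=True)
        if self.possession_times is not None:
            self.possession_times = np.asarray(self.possession_times, dtype=float)
            self.possession_team = np.asarray(self.possession_team, dtype=object)

    def validate(self) -> "EventLog":
        ev = self.events
        if not ev["t"].is_monotonic_increasing:
            raise ValidationError("events are not time-sorted")
        unknown = set(ev["event_type"]) - set(EVENT_TYPES)
        if unknown:
            raise ValidationError(f"unknown event types {sorted(unknown)}")
        starts = ev[ev["event_type"] == "half_start"]["t"].to_numpy()
        ends = ev[ev["event_type"] == "half_end"]["t"].to_numpy()
        if len(starts) != len(ends):
            raise ValidationError(
                f"unmatched half markers: {len(starts)} start(s), {len(ends)} end(s)"
            )
        if np.any(ends <= starts):
            raise ValidationError("half_end does not follow its half_start")
        bounds = self.half_bounds()
        for t in ev[ev["event_type"] == "shot"]["t"]:
            if not any(s <= t <= e for s, e in bounds):
                raise ValidationError(f"shot at t={t} outside every half")
        return self

    def half_bounds(self) -> list[tuple[float, float]]:
        ev = self.events
        starts = ev[ev["event_type"] == "half_start"]["t"].to_numpy(dtype=float)
        ends = ev[ev["event_type"] == "half_end"]["t"].to_numpy(dtype=float)
        return list(zip(starts, ends))

    def shots(self) -> pd.DataFrame:
        return self.events[self.events["event_type"] == "shot"][["t", "team"]].reset_index(drop=True)

    def possession_series(self, start: float, end: float) -> np.ndarray:
        """Per-second possession labels on the integer grid ``start..end``.

        Seconds with no label (before the first gain of a half, or outside
        the stored series) are the empty string.
        """
        grid = np.arange(start, end + 0.5, 1.0)
        labels = np.full(len(grid), "", dtype=object)
        if self.possession_times is not None:
            lookup = {t: lab for t, lab in zip(self.possession_times, self.possession_team)}
            for i, t in enumerate(grid):
                labels[i] = lookup.get(t, "")
            return labels
        gains = self.events[self.events["event_type"] == "possession_gain"]
        for s, e in self.half_bounds():
            sub = gains[(gains["t"] >= s) & (gains["t"] <= e)].sort_values("t")
            for t_g, team in zip(sub["t"], sub["team"]):
                sel = (grid >= t_g) & (grid <= e)
                labels[sel] = team
        return labels


def load_events(path, possession_path=None) -> EventLog:
    """Read an event CSV (``t,team,event_type``) and optional possession CSV (``t,team``)."""
    try:
        df = pd.read_csv(path, keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot parse event file {path}: {exc}") from exc
    for col in ("t", "team", "event_type"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column '{col}'")
    df["t"] = pd.to_numeric(df["t"], errors="raise")
    pt = pteam = None
    if possession_path is not None:
        pdf = pd.read_csv(possession_path, keep_default_na=False)
        pt = pdf["t"].to_numpy(dtype=float)
        pteam = pdf["team"].to_numpy(dtype=object)
    return EventLog(events=df, possession_times=pt, possession_team=pteam).validate()


def write_events(events: EventLog, path, possession_path=None) -> None:
    events.events.to_csv(path, index=False)
    if possession_path is not None and events.possession_times is not None:
        pd.DataFrame({"t": events.possession_times, "team": events.possession_team}).to_csv(
            possession_path, index=False
        )
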