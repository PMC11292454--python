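"""The six per-case team motion features.

Per member, *displacement* is the Euclidean distance between the neck
positions of consecutive frames (pixels per frame step); *trajectory* is the
running sum of displacements (total distance travelled, pixels); *speed* is
displacement divided by elapsed time (pixels/second); *acceleration* is the
first difference of the speed series.  At the team level, the per-transition
mean of member displacements gives the team displacement series, and the
per-transition standard deviation of member speeds gives speed variability.

Irregularity of team motion is measured by symbolic Shannon entropy: the
team displacement series is discretised into a small alphabet (quantile bins
estimated once per case, so windows are comparable), the symbol stream is
cut into nonoverlapping 60-second windows, and the case value is the mean of
the per-window entropies, in bits.  Smooth, slowly drifting motion keeps
each window inside a few bins (low entropy); erratic motion spreads every
window across the whole alphabet (entropy approaching log2(alphabet size)).

Conventions for missing data: a transition is only defined between samples
on adjacent frames, so pairs spanning an unfilled gap are skipped, never
treated as zero motion.  Speeds are additionally defined across short gaps
by dividing by the elapsed time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .tracking import PersonTrack, TeamSession, TrackWarning

__all__ = [
    "DisplacementSeries",
    "MotionFeatureSet",
    "displacement_series",
    "trajectory_total",
    "speed_series",
    "acceleration_series",
    "team_displacement_series",
    "team_speed_variability",
    "symbolize_series",
    "shannon_entropy",
    "windowed_displacement_entropy",
    "compute_feature_set",
]

DEFAULT_N_SYMBOLS = 5
DEFAULT_SCHEME = "quantile"
DEFAULT_WINDOW_S = 60.0


@dataclass(frozen=True)
class DisplacementSeries:
    """Displacement values indexed by the start frame of each transition."""

    frames: np.ndarray   # frame index t of transition t -> t+1
    values: np.ndarray   # pixels per frame step, >= 0
    member_id: str = "team"

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", np.asarray(self.frames, dtype=np.int64))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MotionFeatureSet:
    """The six per-case scalars; NaN marks a feature that was uncomputable."""

    mean_displacement: float        # px / frame step
    mean_trajectory: float          # px
    mean_speed: float               # px / s
    speed_variability: float        # px / s
    mean_abs_acceleration: float    # px/s per frame step
    displacement_entropy: float     # bits

    def as_row(self, case_id: str) -> dict:
        return {
            "case_id": case_id,
            "mean_displacement_px": self.mean_displacement,
            "mean_trajectory_px": self.mean_trajectory,
            "mean_speed_pxs": self.mean_speed,
            "speed_variability_pxs": self.speed_variability,
            "mean_abs_accel": self.mean_abs_acceleration,
            "displacement_entropy_bits": self.displacement_entropy,
        }


def displacement_series(track: PersonTrack) -> DisplacementSeries:
    """Euclidean distance between consecutive-frame neck positions.

    Only pairs of samples on adjacent frames contribute; pairs spanning an
    unfilled gap are skipped.  Fewer than 2 samples yields an empty series
    with a warning.
    """
    if len(track) < 2:
        warnings.warn(
            f"track {track.member_id}: fewer than 2 samples, "
            "empty displacement series", TrackWarning, stacklevel=2,
        )
        return DisplacementSeries(np.empty(0, dtype=np.int64), np.empty(0),
                                  track.member_id)
    adjacent = np.diff(track.frames) == 1
    d = np.linalg.norm(np.diff(track.xy, axis=0), axis=1)
    return DisplacementSeries(track.frames[:-1][adjacent], d[adjacent],
                              track.member_id)


def trajectory_total(track: PersonTrack) -> float:
    """Total distance travelled: the sum of the displacement series (px)."""
    return float(displacement_series(track).values.sum())


def speed_series(track: PersonTrack, fps: float) -> DisplacementSeries:
    """Displacement divided by elapsed time, in pixels/second.

    Unlike :func:`displacement_series`, pairs spanning ``g`` frames remain
    defined: the distance is divided by ``g / fps``.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if len(track) < 2:
        warnings.warn(
            f"track {track.member_id}: fewer than 2 samples, "
            "empty speed series", TrackWarning, stacklevel=2,
        )
        return DisplacementSeries(np.empty(0, dtype=np.int64), np.empty(0),
                                  track.member_id)
    gaps = np.diff(track.frames)
    d = np.linalg.norm(np.diff(track.xy, axis=0), axis=1)
    return DisplacementSeries(track.frames[:-1], d / (gaps / fps), track.member_id)


def acceleration_series(speeds: DisplacementSeries) -> np.ndarray:
    """Signed first differences of a speed series (px/s per frame step)."""
    if len(speeds) < 2:
        return np.empty(0)
    return np.diff(speeds.values)


def team_displacement_series(session: TeamSession) -> DisplacementSeries:
    """Per-transition mean of member displacements ("the team's motion").

    At each frame transition the mean is taken over the members whose
    displacement is defined there; transitions with no contributing member
    are absent from the series.
    """
    frames_all = []
    values_all = []
    for t in session.clipped_tracks():
        if len(t) < 2:
            continue
        s = displacement_series(t)
        frames_all.append(s.frames)
        values_all.append(s.values)
    if not frames_all or sum(len(f) for f in frames_all) == 0:
        warnings.warn(
            f"session {session.case_id}: no member contributes any "
            "displacement", TrackWarning, stacklevel=2,
        )
        return DisplacementSeries(np.empty(0, dtype=np.int64), np.empty(0))
    frames = np.concatenate(frames_all)
    values = np.concatenate(values_all)
    uniq, inverse = np.unique(frames, return_inverse=True)
    sums = np.bincount(inverse, weights=values)
    counts = np.bincount(inverse)
    return DisplacementSeries(uniq, sums / counts)


def team_speed_variability(session: TeamSession, fps: float | None = None) -> float:
    """Mean over time of the within-team standard deviation of member speeds.

    At each frame transition where at least two members have a defined
    speed, the population (ddof=0) standard deviation of those speeds is
    taken; the scalar is the mean over such transitions.  NaN with a warning
    if no transition ever has two contributors.
    """
    fps = session.fps if fps is None else fps
    frames_all = []
    values_all = []
    for t in session.clipped_tracks():
        if len(t) < 2:
            continue
        s = speed_series(t, fps)
        frames_all.append(s.frames)
        values_all.append(s.values)
    if not frames_all:
        warnings.warn(
            f"session {session.case_id}: no speeds available",
            TrackWarning, stacklevel=2,
        )
        return float("nan")
    frames = np.concatenate(frames_all)
    values = np.concatenate(values_all)
    uniq, inverse = np.unique(frames, return_inverse=True)
    counts = np.bincount(inverse)
    sums = np.bincount(inverse, weights=values)
    sq_sums = np.bincount(inverse, weights=values**2)
    multi = counts >= 2
    if not multi.any():
        warnings.warn(
            f"session {session.case_id}: never two members at one "
            "transition; speed variability undefined",
            TrackWarning, stacklevel=2,
        )
        return float("nan")
    mean = sums[multi] / counts[multi]
    var = np.maximum(sq_sums[multi] / counts[multi] - mean**2, 0.0)
    return float(np.mean(np.sqrt(var)))


def symbolize_series(
    values: np.ndarray | DisplacementSeries,
    n_symbols: int = DEFAULT_N_SYMBOLS,
    scheme: str = DEFAULT_SCHEME,
) -> np.ndarray:
    """Discretise a displacement series into symbols 0..n_symbols-1.

    ``quantile`` places bin edges at the series' empirical quantiles
    (computed once over the whole series); ``equal_width`` spans
    ``[min, max]`` evenly.  A value lying exactly on an edge goes to the
    higher bin.  A constant series maps to all-zero symbols.
    """
    if n_symbols < 2:
        raise ValueError("n_symbols must be at least 2")
    if scheme not in ("quantile", "equal_width"):
        raise ValueError(f"unknown symbolization scheme {scheme!r}")
    x = values.values if isinstance(values, DisplacementSeries) else np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot symbolize an empty series")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return np.zeros(x.size, dtype=np.int64)
    if scheme == "quantile":
        edges = np.quantile(x, np.arange(1, n_symbols) / n_symbols)
    else:
        edges = np.linspace(lo, hi, n_symbols + 1)[1:-1]
    # count of edges <= value  ->  values on an edge go to the higher bin
    symbols = np.searchsorted(edges, x, side="right")
    return np.minimum(symbols, n_symbols - 1).astype(np.int64)


def shannon_entropy(symbols: np.ndarray) -> float:
    """Shannon entropy of the observed symbol frequencies, in bits."""
    symbols = np.asarray(symbols)
    if symbols.size == 0:
        return float("nan")
    _, counts = np.unique(symbols, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum() + 0.0)  # +0.0 avoids -0.0


def windowed_displacement_entropy(
    session: TeamSession,
    window_s: float = DEFAULT_WINDOW_S,
    n_symbols: int = DEFAULT_N_SYMBOLS,
    scheme: str = DEFAULT_SCHEME,
) -> float:
    """Mean per-window symbolic entropy of the team displacement series.

    The team displacement series is symbolised once over the whole case (so
    per-window entropies share a common alphabet and bin edges), then split
    into nonoverlapping windows of ``window_s`` seconds of frame transitions;
    each complete window contributes one entropy and the case value is their
    mean.  The trailing partial window is discarded.  A session shorter than
    one window falls back to the whole-series entropy with a warning.
    """
    team = team_displacement_series(session)
    if len(team) == 0:
        return float("nan")
    symbols = symbolize_series(team, n_symbols=n_symbols, scheme=scheme)
    w = int(round(window_s * session.fps))
    if w <= 0:
        raise ValueError("window must span at least one frame transition")
    t0 = int(team.frames[0])
    span = int(team.frames[-1]) - t0 + 1
    n_windows = span // w
    if n_windows == 0:
        warnings.warn(
            f"session {session.case_id}: shorter than one "
            f"{window_s:g}-s window; whole-series entropy used",
            TrackWarning, stacklevel=2,
        )
        return shannon_entropy(symbols)
    window_of = (team.frames - t0) // w
    entropies = [
        shannon_entropy(symbols[window_of == wi])
        for wi in range(n_windows)
        if np.any(window_of == wi)
    ]
    if not entropies:
        return float("nan")
    return float(np.mean(entropies))


def compute_feature_set(
    session: TeamSession,
    window_s: float = DEFAULT_WINDOW_S,
    n_symbols: int = DEFAULT_N_SYMBOLS,
    scheme: str = DEFAULT_SCHEME,
) -> MotionFeatureSet:
    """All six features of a session (restricted to its phase window if set).

    Member-level features (trajectory, speed, |acceleration|) are averaged
    over members so that team size does not inflate them; displacement and
    entropy are computed on the team-mean displacement series.  Any feature
    that cannot be computed is returned as NaN, the others are unaffected.
    """
    tracks = [t for t in session.clipped_tracks() if len(t) >= 2]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", TrackWarning)
        team = team_displacement_series(session)
    mean_displacement = float(team.values.mean()) if len(team) else float("nan")

    if tracks:
        mean_trajectory = float(np.mean([trajectory_total(t) for t in tracks]))
        member_speeds = [speed_series(t, session.fps) for t in tracks]
        mean_speed = float(np.mean([s.values.mean() for s in member_speeds]))
        accels = [acceleration_series(s) for s in member_speeds]
        accel_means = [np.abs(a).mean() for a in accels if a.size]
        mean_abs_accel = float(np.mean(accel_means)) if accel_means else float("nan")
    else:
        mean_trajectory = mean_speed = mean_abs_accel = float("nan")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", TrackWarning)
        variability = team_speed_variability(session)
        entropy = (
            windowed_displacement_entropy(
                session, window_s=window_s, n_symbols=n_symbols, scheme=scheme
            )
            if len(team)
            else float("nan")
        )

    return MotionFeatureSet(
        mean_displacement=mean_displacement,
        mean_trajectory=mean_trajectory,
        mean_speed=mean_speed,
        speed_variability=variability,
        mean_abs_acceleration=mean_abs_accel,
        displacement_entropy=entropy,
    )
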