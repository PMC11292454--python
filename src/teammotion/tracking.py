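"""Per-person neck tracks: association, confidence filtering, outlier
removal and gap interpolation.

Detections in OpenPose output are anonymous — nothing links "person 0" in
one frame to "person 0" in the next — so identities are recovered by greedy
frame-to-frame nearest-neighbour assignment on neck positions.  This is
adequate for a small team of largely station-keeping roles; it makes no
attempt at appearance-based re-identification, and a member returning after
a long absence (shift change) simply starts a new track.

Cleaning is deliberately simple and single-pass: drop low-confidence
samples, drop samples whose per-frame displacement exceeds a robust
median + k x MAD threshold (spurious detections show up as impossible
jumps), then fill short gaps by linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import KeypointFrame, neck_position, TRACK_COLUMNS

__all__ = [
    "PersonTrack",
    "TeamSession",
    "TrackWarning",
    "associate_detections",
    "filter_low_confidence",
    "flag_speed_outliers",
    "interpolate_gaps",
    "preprocess_track",
    "session_from_track_df",
    "session_to_track_df",
]

# default cleaning thresholds
DEFAULT_CONFIDENCE_FLOOR = 0.2
DEFAULT_MAX_JUMP = 100.0  # px per frame
DEFAULT_MAX_GAP = 30      # frames (1 s at 30 fps)
DEFAULT_K_MAD = 5.0


class TrackWarning(UserWarning):
    """Non-fatal preprocessing condition (degenerate or too-short track)."""


@dataclass(frozen=True)
class PersonTrack:
    """One member's neck-position time series.

    ``frames`` are strictly increasing frame indices; gaps are allowed and
    simply absent from the arrays.  ``xy`` is an ``(n, 2)`` pixel array and
    ``confidence`` the per-sample detection confidence.
    """

    member_id: str
    frames: np.ndarray
    xy: np.ndarray
    confidence: np.ndarray
    role: str | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        conf = np.asarray(self.confidence, dtype=float)
        if not (len(frames) == len(xy) == len(conf)):
            raise ValueError("frames, xy and confidence must have equal length")
        if len(frames) > 1 and np.any(np.diff(frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "confidence", conf)

    def __len__(self) -> int:
        return len(self.frames)

    def select(self, mask: np.ndarray) -> "PersonTrack":
        return replace(
            self, frames=self.frames[mask], xy=self.xy[mask],
            confidence=self.confidence[mask],
        )


@dataclass(frozen=True)
class TeamSession:
    """All member tracks of one surgical case on a shared frame clock."""

    case_id: str
    fps: float
    tracks: tuple[PersonTrack, ...]
    phase: tuple[int, int] | None = None  # (start_frame, end_frame) inclusive

    def __post_init__(self) -> None:
        object.__setattr__(self, "tracks", tuple(self.tracks))
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.phase is not None:
            lo, hi = self.phase
            if lo > hi:
                raise ValueError("phase start must not exceed phase end")

    def clipped_tracks(self) -> tuple[PersonTrack, ...]:
        """Tracks restricted to the phase window (all tracks if no phase)."""
        if self.phase is None:
            return self.tracks
        lo, hi = self.phase
        return tuple(
            t.select((t.frames >= lo) & (t.frames <= hi)) for t in self.tracks
        )


# ---------------------------------------------------------------------------
# association


class _OpenTrack:
    __slots__ = ("creation_index", "frames", "xy", "conf", "last_frame")

    def __init__(self, creation_index: int):
        self.creation_index = creation_index
        self.frames: list[int] = []
        self.xy: list[tuple[float, float]] = []
        self.conf: list[float] = []
        self.last_frame = -1

    def append(self, frame: int, x: float, y: float, c: float) -> None:
        self.frames.append(frame)
        self.xy.append((x, y))
        self.conf.append(c)
        self.last_frame = frame


def associate_detections(
    frames: Sequence[KeypointFrame],
    max_jump: float = DEFAULT_MAX_JUMP,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[PersonTrack]:
    """Link anonymous per-frame detections into per-person neck tracks.

    Greedy nearest-neighbour assignment on neck positions: per frame, all
    (open track, detection) pairs are considered in order of increasing
    distance (ties broken by lower track creation index) and matched if the
    distance does not exceed ``max_jump`` pixels.  A detection farther than
    ``max_jump`` from every open track starts a new track; a track
    unmatched for more than ``max_gap`` frames is closed.  Detections
    without a neck position are ignored.

    The gate is a constant radius, deliberately not scaled by the elapsed
    gap: spurious far-away detections must keep starting isolated throwaway
    tracks instead of chaining into phantom members.
    """
    if max_jump <= 0:
        raise ValueError("max_jump must be positive")
    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    n_created = 0
    for frame in frames:
        fi = frame.frame_index
        # close stale tracks
        still_open = []
        for tr in open_tracks:
            if fi - tr.last_frame > max_gap:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        necks = []
        for det in frame.detections:
            pos = neck_position(det)
            if pos is not None:
                necks.append(pos)
        if not necks:
            continue

        pairs = []
        for ti, tr in enumerate(open_tracks):
            lx, ly = tr.xy[-1]
            for di, (x, y, _c) in enumerate(necks):
                d = np.hypot(x - lx, y - ly)
                if d <= max_jump:
                    pairs.append((d, tr.creation_index, ti, di))
        pairs.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for d, _ci, ti, di in pairs:
            if ti in used_tracks or di in used_dets:
                continue
            x, y, c = necks[di]
            open_tracks[ti].append(fi, x, y, c)
            used_tracks.add(ti)
            used_dets.add(di)
        for di, (x, y, c) in enumerate(necks):
            if di not in used_dets:
                tr = _OpenTrack(n_created)
                n_created += 1
                tr.append(fi, x, y, c)
                open_tracks.append(tr)
    closed.extend(open_tracks)
    closed.sort(key=lambda t: t.creation_index)
    return [
        PersonTrack(
            member_id=f"track{t.creation_index:03d}",
            frames=np.array(t.frames, dtype=np.int64),
            xy=np.array(t.xy, dtype=float).reshape(-1, 2),
            confidence=np.array(t.conf, dtype=float),
        )
        for t in closed
    ]


# ---------------------------------------------------------------------------
# cleaning


def filter_low_confidence(track: PersonTrack, floor: float) -> PersonTrack:
    """Drop samples with confidence below ``floor`` (they become gaps)."""
    if not 0.0 <= floor <= 1.0:
        raise ValueError("confidence floor must lie in [0, 1]")
    return track.select(track.confidence >= floor)


def flag_speed_outliers(
    track: PersonTrack, fps: float = 30.0, k_mad: float = DEFAULT_K_MAD
) -> PersonTrack:
    """Remove samples reached by an implausible jump.

    The per-frame displacement (Euclidean distance between consecutive
    retained samples, divided by the elapsed frame count) is computed for
    every sample after the first; a sample is removed iff its incoming
    displacement exceeds ``median + k_mad x MAD`` of the track's displacement
    distribution.  The rule is single-pass: the threshold is computed once
    on the original series.  Tracks with fewer than 3 samples are returned
    unchanged with a warning.
    """
    if k_mad <= 0:
        raise ValueError("k_mad must be positive")
    if len(track) < 3:
        warnings.warn(
            f"track {track.member_id}: fewer than 3 samples, outlier "
            "filtering skipped", TrackWarning, stacklevel=2,
        )
        return track
    gaps = np.diff(track.frames)
    disp = np.linalg.norm(np.diff(track.xy, axis=0), axis=1) / gaps
    med = np.median(disp)
    mad = np.median(np.abs(disp - med))
    threshold = med + k_mad * mad
    keep = np.ones(len(track), dtype=bool)
    keep[1:] = disp <= threshold
    return track.select(keep)


def interpolate_gaps(track: PersonTrack, max_gap: int = DEFAULT_MAX_GAP) -> PersonTrack:
    """Fill short gaps by linear interpolation between flanking samples.

    A gap of ``g`` missing frames between consecutive samples is filled iff
    ``g <= max_gap``; filled samples get the minimum of the two flanking
    confidences.  Longer gaps, and anything before the first or after the
    last sample, are never filled.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    if len(track) < 2 or max_gap == 0:
        return track
    f, xy, c = track.frames, track.xy, track.confidence
    d = np.diff(f)
    gap_sizes = d - 1
    fill = (gap_sizes > 0) & (gap_sizes <= max_gap)
    if not fill.any():
        return track
    pair_idx = np.where(fill)[0]
    g_fill = gap_sizes[pair_idx]
    # per filled frame: the index of its left flank and its 1..g offset
    left = np.repeat(pair_idx, g_fill)
    start = np.concatenate([[0], np.cumsum(g_fill)[:-1]])
    seq = np.arange(g_fill.sum()) - np.repeat(start, g_fill) + 1
    w = seq / d[left]
    new_frames = f[left] + seq
    new_xy = xy[left] + w[:, None] * (xy[left + 1] - xy[left])
    new_conf = np.minimum(c[left], c[left + 1])
    all_frames = np.concatenate([f, new_frames])
    order = np.argsort(all_frames, kind="stable")
    return replace(
        track,
        frames=all_frames[order],
        xy=np.concatenate([xy, new_xy])[order],
        confidence=np.concatenate([c, new_conf])[order],
    )


def preprocess_track(
    track: PersonTrack,
    fps: float = 30.0,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    k_mad: float = DEFAULT_K_MAD,
    max_gap: int = DEFAULT_MAX_GAP,
) -> PersonTrack:
    """Confidence filter, outlier removal and gap interpolation, in order."""
    track = filter_low_confidence(track, confidence_floor)
    if len(track) >= 3:
        track = flag_speed_outliers(track, fps=fps, k_mad=k_mad)
    track = interpolate_gaps(track, max_gap=max_gap)
    return track


# ---------------------------------------------------------------------------
# tabular round-trip


def session_to_track_df(session: TeamSession) -> pd.DataFrame:
    """Long-format table of a session's samples (one row per member-frame)."""
    parts = []
    for t in session.tracks:
        parts.append(
            pd.DataFrame(
                {
                    "case_id": session.case_id,
                    "member_id": t.member_id,
                    "frame_index": t.frames,
                    "x": t.xy[:, 0],
                    "y": t.xy[:, 1],
                    "confidence": t.confidence,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(parts, ignore_index=True)[TRACK_COLUMNS]


def session_from_track_df(
    df: pd.DataFrame, case_id: str, fps: float = 30.0,
    phase: tuple[int, int] | None = None,
) -> TeamSession:
    sub = df[df["case_id"] == case_id]
    tracks = []
    for member_id, g in sub.groupby("member_id", sort=True):
        g = g.sort_values("frame_index")
        tracks.append(
            PersonTrack(
                member_id=str(member_id),
                frames=g["frame_index"].to_numpy(),
                xy=g[["x", "y"]].to_numpy(),
                confidence=g["confidence"].to_numpy(),
            )
        )
    return TeamSession(case_id=case_id, fps=fps, tracks=tuple(tracks), phase=phase)
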