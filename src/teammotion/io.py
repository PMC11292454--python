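"""Reading and validation of OpenPose-dialect keypoint files and tabular data.

OpenPose writes one JSON file per video frame, each containing a ``people``
list whose entries carry a flat ``pose_keypoints_2d`` array of
``(x, y, confidence)`` triples.  Three skeleton layouts are supported, told
apart by the array length: COCO-17 (51 numbers), COCO-18 (54) and BODY-25
(75).  An all-zero ``(0, 0, 0)`` triple is OpenPose's convention for an
undetected keypoint and is preserved as a missing marker, never as a
coordinate.

The whole-body position of a person is summarised by the *neck* keypoint.
COCO-18 and BODY-25 place the neck at keypoint index 1; COCO-17 has no neck
keypoint, so it is synthesised as the midpoint of the two shoulders with
confidence equal to the smaller of the two shoulder confidences.

Coordinates are pixels in image space (origin top-left, x right, y down);
no normalisation by image size is applied.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Layout",
    "PersonDetection",
    "KeypointFrame",
    "LayoutError",
    "FrameOrderError",
    "read_openpose_frames",
    "neck_position",
    "read_track_csv",
    "write_track_csv",
    "read_feature_table",
    "write_feature_table",
    "read_ratings_csv",
    "read_covariates_csv",
    "FEATURE_COLUMNS",
    "TRACK_COLUMNS",
]


class Layout(enum.Enum):
    """Supported OpenPose skeleton layouts, keyed by keypoint count."""

    COCO17 = 17
    COCO18 = 18
    BODY25 = 25

    @property
    def n_keypoints(self) -> int:
        return self.value


#: keypoint index of the neck in layouts that have one
_NECK_INDEX = {Layout.COCO18: 1, Layout.BODY25: 1}
#: left/right shoulder indices in COCO-17 (no neck keypoint)
_COCO17_SHOULDERS = (5, 6)

_LAYOUT_BY_LENGTH = {3 * l.n_keypoints: l for l in Layout}


class LayoutError(ValueError):
    """Raised for keypoint arrays whose length matches no supported layout."""


class FrameOrderError(ValueError):
    """Raised when frame indices are not strictly increasing."""


@dataclass(frozen=True)
class PersonDetection:
    """One person's keypoints in one frame.

    ``keypoints`` is an ``(n, 3)`` float array of ``(x, y, confidence)``
    rows; an all-zero row denotes an undetected keypoint.
    """

    keypoints: np.ndarray
    layout: Layout
    person_index: int = 0

    def __post_init__(self) -> None:
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.ndim != 2 or kp.shape[1] != 3:
            raise ValueError(f"keypoints must be (n, 3), got {kp.shape}")
        if kp.shape[0] != self.layout.n_keypoints:
            raise LayoutError(
                f"layout {self.layout.name} expects {self.layout.n_keypoints} "
                f"keypoints, got {kp.shape[0]}"
            )
        conf = kp[:, 2]
        if np.any((conf < 0) | (conf > 1)):
            raise ValueError("confidences must lie in [0, 1]")
        object.__setattr__(self, "keypoints", kp)

    def is_missing(self, index: int) -> bool:
        """True if the keypoint at ``index`` is the all-zero missing marker."""
        return bool(np.all(self.keypoints[index] == 0.0))


@dataclass(frozen=True)
class KeypointFrame:
    """All detections in one video frame."""

    frame_index: int
    detections: tuple[PersonDetection, ...] = ()
    fps: float = 30.0

    @property
    def timestamp(self) -> float:
        return self.frame_index / self.fps


def detect_layout(flat_length: int) -> Layout:
    """Map a flat keypoint-array length (3 x keypoint count) to its layout."""
    try:
        return _LAYOUT_BY_LENGTH[flat_length]
    except KeyError:
        raise LayoutError(
            f"keypoint array of length {flat_length} matches no supported "
            f"layout (expected one of {sorted(_LAYOUT_BY_LENGTH)})"
        ) from None


def person_from_flat(flat: Sequence[float], person_index: int = 0) -> PersonDetection:
    """Build a :class:`PersonDetection` from a flat x,y,c,... array."""
    arr = np.asarray(flat, dtype=float)
    layout = detect_layout(arr.size)
    return PersonDetection(arr.reshape(-1, 3), layout, person_index)


_FRAME_SUFFIX_RE = re.compile(r"(\d+)(?:_keypoints)?\.json$")


def _frame_index_from_name(path: Path) -> int:
    m = _FRAME_SUFFIX_RE.search(path.name)
    if m is None:
        raise ValueError(
            f"cannot parse a frame index from file name {path.name!r}; "
            "expected a numeric suffix like 'case1_000000000012_keypoints.json'"
        )
    return int(m.group(1))


def _frame_from_record(record: dict, frame_index: int, fps: float) -> KeypointFrame:
    people = record.get("people", [])
    detections = tuple(
        person_from_flat(p["pose_keypoints_2d"], person_index=i)
        for i, p in enumerate(people)
    )
    return KeypointFrame(frame_index=frame_index, detections=detections, fps=fps)


def read_openpose_frames(source: str | Path, fps: float = 30.0) -> list[KeypointFrame]:
    """Read OpenPose-dialect keypoint output into ordered frames.

    ``source`` may be a directory of per-frame ``*_keypoints.json`` files
    (frame index parsed from the numeric file-name suffix) or a single
    JSON-lines file with one frame record per line (an optional
    ``frame_index`` field overrides the line number).

    Frames are returned ordered by frame index.  A frame with an empty
    ``people`` list yields a frame with zero detections; all-zero keypoint
    triples are preserved as missing markers.

    Raises
    ------
    LayoutError
        If a person's keypoint array has an unsupported length.
    FrameOrderError
        If frame indices are not strictly increasing.
    """
    src = Path(source)
    if not src.exists():
        raise FileNotFoundError(f"keypoint source {src} does not exist")
    frames: list[KeypointFrame] = []
    if src.is_dir():
        entries = sorted(
            ((_frame_index_from_name(p), p) for p in src.glob("*.json")),
            key=lambda t: t[0],
        )
        for frame_index, path in entries:
            with open(path) as fh:
                record = json.load(fh)
            frames.append(_frame_from_record(record, frame_index, fps))
    else:
        with open(src) as fh:
            for lineno, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                record = json.loads(line)
                frame_index = int(record.get("frame_index", lineno))
                frames.append(_frame_from_record(record, frame_index, fps))
        frames.sort(key=lambda f: f.frame_index)
    indices = [f.frame_index for f in frames]
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise FrameOrderError("frame indices are not strictly increasing")
    return frames


def neck_position(d: PersonDetection) -> tuple[float, float, float] | None:
    """Neck position ``(x, y, confidence)`` of a detection, or None if missing.

    COCO-18 and BODY-25 return their neck keypoint verbatim.  COCO-17 has no
    neck, so the midpoint of the left and right shoulders is used, with
    confidence equal to the minimum of the two.  If every contributing
    keypoint is undetected (all-zero triple), the result is None — a missing
    position is a value, never a fabricated coordinate.
    """
    if d.layout in _NECK_INDEX:
        idx = _NECK_INDEX[d.layout]
        if d.is_missing(idx):
            return None
        x, y, c = d.keypoints[idx]
        return float(x), float(y), float(c)
    li, ri = _COCO17_SHOULDERS
    lmiss, rmiss = d.is_missing(li), d.is_missing(ri)
    if lmiss and rmiss:
        return None
    if lmiss or rmiss:
        # one shoulder only: no midpoint can be formed without fabricating
        # the other side, so treat as missing
        return None
    lx, ly, lc = d.keypoints[li]
    rx, ry, rc = d.keypoints[ri]
    return float((lx + rx) / 2), float((ly + ry) / 2), float(min(lc, rc))


# ---------------------------------------------------------------------------
# tabular formats

TRACK_COLUMNS = ["case_id", "member_id", "frame_index", "x", "y", "confidence"]

FEATURE_COLUMNS = [
    "case_id",
    "mean_displacement_px",
    "mean_trajectory_px",
    "mean_speed_pxs",
    "speed_variability_pxs",
    "mean_abs_accel",
    "displacement_entropy_bits",
]

RATING_COLUMNS = ["case_id", "rater_id", "item_id", "score"]
COVARIATE_COLUMNS = ["case_id", "bypass_minutes", "morbidity30d"]

#: repr-roundtrip float format used by every CSV writer (17 significant
#: digits reproduce IEEE doubles exactly)
_FLOAT_FMT = "%.17g"


def write_track_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format track table (one row per member-frame sample)."""
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    df.loc[:, TRACK_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_track_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track CSV {path} missing columns: {sorted(missing)}")
    return df.loc[:, TRACK_COLUMNS]


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the per-case wide feature table with full float precision.

    One row per case, fixed column order; duplicate case ids are rejected.
    ``read_feature_table(write_feature_table(x)) == x`` bit-for-bit.
    """
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"duplicate case ids: {dupes}")
    df.loc[:, FEATURE_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature CSV {path} missing columns: {sorted(missing)}")
    return df.loc[:, FEATURE_COLUMNS]


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format ratings table (case x rater x item, scores 1-4)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(RATING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ratings CSV {path} missing columns: {sorted(missing)}")
    scores = df["score"]
    if not np.all(np.isin(scores, [1, 2, 3, 4])):
        bad = sorted(set(scores) - {1, 2, 3, 4})
        raise ValueError(f"scores outside the 1-4 scale: {bad}")
    return df.loc[:, RATING_COLUMNS]


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"covariates CSV {path} missing columns: {sorted(missing)}")
    if (df[["bypass_minutes", "morbidity30d"]] < 0).any().any():
        raise ValueError("covariates must be non-negative")
    return df.loc[:, COVARIATE_COLUMNS]
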