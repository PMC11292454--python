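"""Synthetic operating-room team cohorts with known ground truth.

No public dataset of intraoperative pose keypoints with paired NOTSS
ratings exists, so the pipeline is exercised on simulated cohorts whose
generating parameters are returned alongside the data: every downstream
estimate can be checked against the truth that produced it.

Each case is a 4-member team (surgeon, anesthesiologist, perfusionist,
scrub nurse) filmed at 30 fps for one analysis phase.  A member's neck
position follows a mean-reverting walk around a role-specific anchor in a
1920x1080 frame,

    x_{t+1} = x_t + lam * (anchor - x_t) + a * (kappa * s_t + (1 - kappa) * u_t)

where ``s_t`` is a team-shared smooth innovation, ``u_t`` an individual
innovation mixing a smooth component (weight ``1 - eps``) and a white
heavy-tailed jump component (weight ``eps``), and ``a`` scales everything
to pixels.  Smooth components carry a slowly varying log-normal amplitude
envelope, so quiet and busy minutes alternate the way OR activity does.
The three per-case latents drive the features monotonically:

* erraticity ``eps``   -> windowed displacement entropy (white jumps spread
  every 60-s window across the whole symbol alphabet);
* activity ``a``       -> trajectory, displacement, speed (linear scale);
* coordination ``kappa`` -> (inversely) speed variability (shared motion
  makes member speeds agree).

Missing detections and spurious outlier detections are injected at
configurable rates.  Raters are simulated at item level: a latent team
skill, linear in z-scored features, is mapped to the 1-4 NOTSS scale and
perturbed by per-rater biases and item noise, then rounded and clipped.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .features import compute_feature_set
from .io import FEATURE_COLUMNS
from .tracking import PersonTrack, TeamSession, preprocess_track

__all__ = [
    "SimulationConfig",
    "ROLE_ANCHORS",
    "simulate_team_session",
    "simulate_notss_ratings",
    "simulate_covariates",
    "simulate_cohort_tables",
    "simulate_cohort",
]

FRAME_SIZE = (1920.0, 1080.0)

#: role-specific anchor positions (px) in the camera frame
ROLE_ANCHORS = {
    "surgeon": (960.0, 430.0),
    "anesthesiologist": (520.0, 300.0),
    "perfusionist": (1450.0, 640.0),
    "scrub_nurse": (1100.0, 720.0),
}

# internal dynamics constants (per-frame, at 30 fps)
_LAMBDA = 0.005        # mean-reversion rate toward the role anchor
_RHO_SMOOTH = 0.95     # AR(1) coefficient of smooth innovations
_RHO_ENVELOPE = 0.9998  # AR(1) of the log-amplitude envelope (~2-3 min scale)
_SIGMA_ENVELOPE = 1.0  # stationary SD of the log-amplitude envelope
_JUMP_DF = 3           # Student-t df of the heavy-tailed jump component

# rating-model constants; the anchor sits in the upper half of the 1-4
# scale — experienced OR teams average NOTSS ratings around 3.2
_RATING_MIDPOINT = 3.2
_RATING_SCALE = 0.45   # raw rating units per unit of latent skill

_FEATURE_COLS = FEATURE_COLUMNS[1:]  # the six feature columns


def _default_betas() -> dict[str, float]:
    # effect pattern mirroring the study conditions: trajectory loads
    # positively on skill, displacement entropy negatively
    return {"mean_trajectory_px": 0.6, "displacement_entropy_bits": -0.6}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated cohort.

    Defaults emulate the published cohort: 30 cases, 4-member teams at
    30 fps, an analysis phase of about 8 minutes (log-normal spread across
    cases), occasional missed and spurious detections, and 3 noisy raters
    whose scores are linked to latent team skill through ``betas``.
    """

    n_cases: int = 30
    n_members: int = 4
    duration_s: float = 480.0       # median phase length (s)
    duration_sigma: float = 0.3     # log-normal sigma of per-case duration
    fps: float = 30.0
    erraticity: float | None = None   # eps in [0,1]; None -> per-case U(0.15, 0.85)
    activity: float = 3.0             # median innovation scale a (px)
    activity_sigma: float = 0.4       # log-normal sigma of per-case activity
    coordination: float | None = None  # kappa in [0,1]; None -> per-case U(0.2, 0.8)
    missing_rate: float = 0.05
    outlier_rate: float = 0.01
    n_raters: int = 3
    rater_sd: float = 0.5           # item-level rating noise (raw 1-4 units)
    rater_bias_sd: float = 0.3      # SD of per-rater additive bias
    skill_noise_sd: float = 0.6     # latent-skill noise not explained by motion
    betas: dict[str, float] = field(default_factory=_default_betas)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("erraticity", "coordination"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.activity < 0:
            raise ValueError("activity must be non-negative")
        unknown = set(self.betas) - set(_FEATURE_COLS)
        if unknown:
            raise ValueError(f"betas refer to unknown features: {sorted(unknown)}")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _case_rng(cfg: SimulationConfig, case_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed) % 2**31, 1, int(case_index)])
    )


def _ratings_rng(cfg: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % 2**31, 2]))


def _cov_rng(cfg: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % 2**31, 3]))


def _ar1(rng: np.random.Generator, shape: tuple[int, ...], rho: float) -> np.ndarray:
    """AR(1) noise with unit stationary variance along axis 0."""
    w = rng.standard_normal(shape)
    return lfilter([math.sqrt(1.0 - rho * rho)], [1.0, -rho], w, axis=0)


def _envelope(rng: np.random.Generator, n: int) -> np.ndarray:
    """Slowly varying log-normal amplitude with unit mean."""
    z = _SIGMA_ENVELOPE * _ar1(rng, (n,), _RHO_ENVELOPE)
    return np.exp(z - 0.5 * _SIGMA_ENVELOPE**2)


def _member_roles(n_members: int) -> list[str]:
    roles = list(ROLE_ANCHORS)
    return [roles[i % len(roles)] for i in range(n_members)]


def simulate_team_session(
    cfg: SimulationConfig, case_index: int
) -> tuple[TeamSession, dict]:
    """One case's team session plus its generating latent parameters.

    Reproducible: the same ``(cfg.seed, case_index)`` always yields the same
    session bit-for-bit.
    """
    rng = _case_rng(cfg, case_index)
    eps = (
        cfg.erraticity
        if cfg.erraticity is not None
        else float(rng.uniform(0.15, 0.85))
    )
    kappa = (
        cfg.coordination
        if cfg.coordination is not None
        else float(rng.uniform(0.2, 0.8))
    )
    a = float(cfg.activity * rng.lognormal(0.0, cfg.activity_sigma))
    duration = float(cfg.duration_s * rng.lognormal(0.0, cfg.duration_sigma))
    n_frames = max(int(round(duration * cfg.fps)), 3)

    roles = _member_roles(cfg.n_members)
    # one session-wide activity envelope: quiet and busy minutes are shared
    # by the whole team, which is what makes smooth cases low-entropy
    envelope = _envelope(rng, n_frames - 1)[:, None]
    shared = envelope * _ar1(rng, (n_frames - 1, 2), _RHO_SMOOTH)
    tracks = []
    for m, role in enumerate(roles):
        anchor = np.array(ROLE_ANCHORS[role])
        if m >= len(ROLE_ANCHORS):  # extra members share anchors, offset a bit
            anchor = anchor + np.array([40.0 * (m // len(ROLE_ANCHORS)), 25.0])
        smooth = envelope * _ar1(rng, (n_frames - 1, 2), _RHO_SMOOTH)
        jump = rng.standard_t(_JUMP_DF, (n_frames - 1, 2)) / math.sqrt(_JUMP_DF)
        individual = (1.0 - eps) * smooth + eps * jump
        step = a * (kappa * shared + (1.0 - kappa) * individual)
        # start-position jitter scales with the motion scale so that a = 0
        # yields an exactly motionless team
        y0 = rng.normal(0.0, 1.7 * a, size=2)
        inp = np.vstack([y0, step])
        pos = anchor + lfilter([1.0], [1.0, -(1.0 - _LAMBDA)], inp, axis=0)
        # image coordinates cannot leave the camera frame
        np.clip(pos[:, 0], 0.0, FRAME_SIZE[0], out=pos[:, 0])
        np.clip(pos[:, 1], 0.0, FRAME_SIZE[1], out=pos[:, 1])

        keep = rng.random(n_frames) >= cfg.missing_rate
        frames = np.arange(n_frames)[keep]
        xy = pos[keep]
        conf = rng.beta(8.0, 2.0, size=keep.sum())
        if cfg.outlier_rate > 0 and len(frames):
            spurious = rng.random(len(frames)) < cfg.outlier_rate
            n_sp = int(spurious.sum())
            if n_sp:
                xy = xy.copy()
                xy[spurious, 0] = rng.uniform(0.0, FRAME_SIZE[0], n_sp)
                xy[spurious, 1] = rng.uniform(0.0, FRAME_SIZE[1], n_sp)
                conf[spurious] = rng.uniform(0.25, 0.7, n_sp)
        tracks.append(
            PersonTrack(
                member_id=f"member{m:02d}",
                frames=frames,
                xy=xy,
                confidence=conf,
                role=role,
            )
        )
    session = TeamSession(
        case_id=f"case{case_index:03d}", fps=cfg.fps, tracks=tuple(tracks)
    )
    truth = {
        "case_id": session.case_id,
        "erraticity": eps,
        "activity": a,
        "coordination": kappa,
        "duration_s": n_frames / cfg.fps,
        "n_frames": n_frames,
    }
    return session, truth


def simulate_notss_ratings(
    true_features: pd.DataFrame, cfg: SimulationConfig
) -> tuple[pd.DataFrame, dict]:
    """Item-level NOTSS ratings linked to motion features via latent skill.

    Latent skill ``S = sum_f beta_f z(feature_f) + noise``; each rater's
    item score is the latent skill mapped to the middle of the 1-4 scale,
    plus a per-rater bias and item noise, rounded and clipped to {1..4}.
    Returns the long-format rating table and a ground-truth dict including
    the implied per-feature linear coefficient of the expected total score
    on the raw (un-z-scored) feature.
    """
    from .stats import ALL_ITEMS  # local import to avoid a cycle

    missing = set(_FEATURE_COLS) - set(true_features.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    if true_features[_FEATURE_COLS].isna().any().any():
        raise ValueError("feature table must be complete")

    rng = _ratings_rng(cfg)
    n = len(true_features)
    skill = np.zeros(n)
    implied = {}
    for colname in _FEATURE_COLS:
        beta = cfg.betas.get(colname, 0.0)
        x = true_features[colname].to_numpy(dtype=float)
        sd = x.std()
        if beta != 0.0 and sd > 0:
            skill += beta * (x - x.mean()) / sd
            implied[colname] = _RATING_SCALE * beta / sd
        else:
            implied[colname] = 0.0
    skill += rng.normal(0.0, cfg.skill_noise_sd, n)

    biases = rng.normal(0.0, cfg.rater_bias_sd, cfg.n_raters)
    raw = (
        _RATING_MIDPOINT
        + _RATING_SCALE * skill[:, None, None]
        + biases[None, :, None]
        + rng.normal(0.0, cfg.rater_sd, (n, cfg.n_raters, len(ALL_ITEMS)))
    )
    scores = np.clip(np.rint(raw), 1, 4).astype(int)

    case_ids = true_features["case_id"].to_numpy()
    rows = {
        "case_id": np.repeat(case_ids, cfg.n_raters * len(ALL_ITEMS)),
        "rater_id": np.tile(
            np.repeat([f"rater{r}" for r in range(cfg.n_raters)], len(ALL_ITEMS)),
            n,
        ),
        "item_id": np.tile(ALL_ITEMS, n * cfg.n_raters),
        "score": scores.ravel(),
    }
    truth = {
        "betas": {c: float(cfg.betas.get(c, 0.0)) for c in _FEATURE_COLS},
        "implied_total_coefficients": implied,
        "latent_skill": skill.tolist(),
        "rater_biases": biases.tolist(),
        "rating_scale": _RATING_SCALE,
        "rating_midpoint": _RATING_MIDPOINT,
    }
    return pd.DataFrame(rows), truth


def expected_total_score(
    features: pd.DataFrame,
    cfg: SimulationConfig,
    rater_biases: np.ndarray | list[float] | None = None,
) -> np.ndarray:
    """Exact per-case expectation of the total score under the rating model.

    An item score is ``clip(round(lin + bias_r + e), 1, 4)`` with ``lin``
    the latent linear predictor and ``e`` Gaussian noise pooling the
    case-level skill noise and the item-level rater noise.  Its expectation
    is a sum of Gaussian threshold probabilities,

        E[score] = 1 + sum_{k=1..3} Phi((lin + bias_r - (k + 1/2)) / sigma)

    which makes the expected total a smooth, mildly compressive function of
    the linear predictor — the discretisation attenuates extreme cases.
    Recovery checks must compare fitted coefficients against this
    expectation, not against the raw linear predictor.
    """
    from scipy.stats import norm

    z = np.zeros(len(features))
    for colname in _FEATURE_COLS:
        beta = cfg.betas.get(colname, 0.0)
        if beta == 0.0:
            continue
        x = features[colname].to_numpy(dtype=float)
        sd = x.std()
        if sd > 0:
            z += beta * (x - x.mean()) / sd
    lin = _RATING_MIDPOINT + _RATING_SCALE * z
    sigma = math.hypot(_RATING_SCALE * cfg.skill_noise_sd, cfg.rater_sd)
    biases = (
        np.zeros(cfg.n_raters) if rater_biases is None
        else np.asarray(rater_biases, dtype=float)
    )
    expected = np.zeros(len(features))
    for b in biases:
        per_rater = np.ones(len(features))
        for k in (1, 2, 3):
            per_rater += norm.cdf((lin + b - (k + 0.5)) / sigma)
        expected += per_rater / len(biases)
    return expected


def implied_adjusted_coefficients(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    feature: str,
    cfg: SimulationConfig,
    rater_biases: np.ndarray | list[float] | None = None,
) -> dict[str, float]:
    """Generating values for the single-feature covariate-adjusted regression.

    When the analysis regresses the total score on one feature plus the
    clinical covariates, the estimand of that design is the projection of
    the expected total score (see :func:`expected_total_score`) onto the
    design matrix ``[1, feature, bypass, morbidity]`` — including any
    omitted-variable contribution from correlated features and the
    attenuation of the discrete 1-4 scale.  No outcome noise enters, so an
    unbiased fit recovers exactly these coefficients on average.
    """
    merged = features.merge(covariates, on="case_id")
    expected_total = expected_total_score(merged, cfg, rater_biases)
    X = np.column_stack(
        [
            np.ones(len(merged)),
            merged[feature].to_numpy(dtype=float),
            merged["bypass_minutes"].to_numpy(dtype=float),
            merged["morbidity30d"].to_numpy(dtype=float),
        ]
    )
    coefs, *_ = np.linalg.lstsq(X, expected_total, rcond=None)
    return {
        "const": float(coefs[0]),
        feature: float(coefs[1]),
        "bypass_minutes": float(coefs[2]),
        "morbidity30d": float(coefs[3]),
    }


def simulate_covariates(cfg: SimulationConfig, case_ids: list[str]) -> pd.DataFrame:
    """Clinical covariates on realistic scales (bypass ~112 min median)."""
    rng = _cov_rng(cfg)
    n = len(case_ids)
    return pd.DataFrame(
        {
            "case_id": case_ids,
            "bypass_minutes": rng.lognormal(math.log(112.0), 0.25, n),
            "morbidity30d": rng.lognormal(math.log(6.9), 0.35, n),
        }
    )


def simulate_cohort_tables(
    cfg: SimulationConfig, preprocess: bool = True
) -> dict:
    """In-memory cohort: sessions -> features, ratings, covariates, truth.

    The per-case feature values are computed by the real feature pipeline
    on the simulated sessions (optionally after the standard track
    cleaning), so downstream statistics see exactly what the pipeline
    would produce.
    """
    rows = []
    case_truths = []
    for i in range(cfg.n_cases):
        session, truth = simulate_team_session(cfg, i)
        if preprocess:
            session = TeamSession(
                case_id=session.case_id,
                fps=session.fps,
                tracks=tuple(
                    preprocess_track(t, fps=session.fps) for t in session.tracks
                ),
                phase=session.phase,
            )
        fs = compute_feature_set(session)
        rows.append(fs.as_row(session.case_id))
        case_truths.append(truth)
    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    ratings, rating_truth = simulate_notss_ratings(features, cfg)
    covariates = simulate_covariates(cfg, features["case_id"].tolist())
    return {
        "features": features,
        "ratings": ratings,
        "covariates": covariates,
        "truth": {"cases": case_truths, "ratings": rating_truth},
    }


# ---------------------------------------------------------------------------
# on-disk cohort in the OpenPose dialect

_COCO18_NECK = 1


def _session_to_jsonl(session: TeamSession, path: Path) -> None:
    """Write a session as one JSON-lines file of COCO-18 frame records."""
    per_frame: dict[int, list[tuple[float, float, float]]] = {}
    for t in session.tracks:
        for f, (x, y), c in zip(t.frames, t.xy, t.confidence):
            per_frame.setdefault(int(f), []).append((float(x), float(y), float(c)))
    last = max(per_frame) if per_frame else -1
    with open(path, "w") as fh:
        for fi in range(last + 1):
            people = []
            for x, y, c in per_frame.get(fi, []):
                flat = [0.0] * (18 * 3)
                flat[3 * _COCO18_NECK : 3 * _COCO18_NECK + 3] = [x, y, c]
                people.append({"pose_keypoints_2d": flat})
            fh.write(json.dumps({"frame_index": fi, "people": people}) + "\n")


def simulate_cohort(cfg: SimulationConfig, out_dir: str | Path) -> dict:
    """Write a complete self-consistent input set for the end-to-end pipeline.

    Produces ``keypoints/<case>.jsonl`` (OpenPose dialect, COCO-18 layout,
    undetected keypoints as all-zero triples), ``ratings.csv``,
    ``covariates.csv`` and ``ground_truth.json`` under ``out_dir`` and
    returns the paths plus the in-memory tables.
    """
    out = Path(out_dir)
    kp_dir = out / "keypoints"
    kp_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    case_truths = []
    for i in range(cfg.n_cases):
        session, truth = simulate_team_session(cfg, i)
        _session_to_jsonl(session, kp_dir / f"{session.case_id}.jsonl")
        cleaned = TeamSession(
            case_id=session.case_id,
            fps=session.fps,
            tracks=tuple(
                preprocess_track(t, fps=session.fps) for t in session.tracks
            ),
        )
        fs = compute_feature_set(cleaned)
        rows.append(fs.as_row(session.case_id))
        case_truths.append(truth)
    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    ratings, rating_truth = simulate_notss_ratings(features, cfg)
    covariates = simulate_covariates(cfg, features["case_id"].tolist())

    ratings_path = out / "ratings.csv"
    covariates_path = out / "covariates.csv"
    truth_path = out / "ground_truth.json"
    ratings.to_csv(ratings_path, index=False)
    covariates.to_csv(covariates_path, index=False, float_format="%.17g")
    truth = {"cases": case_truths, "ratings": rating_truth,
             "config": {**dataclasses.asdict(cfg)}}
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1)
    return {
        "keypoints_dir": kp_dir,
        "ratings_csv": ratings_path,
        "covariates_csv": covariates_path,
        "ground_truth_json": truth_path,
        "features": features,
        "ratings": ratings,
        "covariates": covariates,
        "truth": truth,
    }
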