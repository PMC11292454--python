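"""End-to-end orchestration: extract -> features -> stats, with reporting.

The pipeline stages are pure functions of their inputs and configuration;
every number in the summary JSON is produced by a stats-module operation,
the orchestration layer only routes data and writes artifacts.  Intermediate
artifacts (cleaned tracks, per-case features) are always written so stages
can be inspected or resumed individually.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .features import (
    DEFAULT_N_SYMBOLS,
    DEFAULT_SCHEME,
    DEFAULT_WINDOW_S,
    compute_feature_set,
)
from .stats import (
    associate,
    average_notss,
    fit_adjusted_regression,
    icc_two_way_mixed_consistency,
    ks_normality,
    notss_case_rater_matrix,
)
from .tracking import (
    DEFAULT_CONFIDENCE_FLOOR,
    DEFAULT_K_MAD,
    DEFAULT_MAX_GAP,
    DEFAULT_MAX_JUMP,
    TeamSession,
    associate_detections,
    preprocess_track,
    session_from_track_df,
    session_to_track_df,
)

__all__ = ["PipelineConfig", "run_pipeline", "extract_sessions", "compute_features",
           "run_stats"]

log = logging.getLogger("teammotion")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; mirrors the CLI flags and config file."""

    keypoints_dir: str | None = None   # dir of <case>.jsonl or per-case subdirs
    track_csv: str | None = None       # alternative long-format input
    clean_tracks: bool = True          # False: track_csv is already cleaned
    ratings_csv: str | None = None
    covariates_csv: str | None = None
    out_dir: str = "results"
    fps: float = 30.0
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR
    max_jump: float = DEFAULT_MAX_JUMP
    max_gap: int = DEFAULT_MAX_GAP
    k_mad: float = DEFAULT_K_MAD
    min_track_s: float = 5.0  # drop cleaned tracks shorter than this (0: keep all)
    n_symbols: int = DEFAULT_N_SYMBOLS
    scheme: str = DEFAULT_SCHEME
    window_s: float = DEFAULT_WINDOW_S
    method: str = "spearman"
    bh: bool = False
    regress_all: bool = False
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML or JSON config file; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _discover_cases(kp_dir: Path) -> list[tuple[str, Path]]:
    cases = [(p.stem, p) for p in sorted(kp_dir.glob("*.jsonl"))]
    cases += [(p.name, p) for p in sorted(kp_dir.iterdir())
              if p.is_dir() and any(p.glob("*.json"))]
    if not cases:
        raise FileNotFoundError(
            f"no keypoint inputs (case .jsonl files or per-case directories "
            f"of frame JSONs) found under {kp_dir}"
        )
    return cases


def extract_sessions(cfg: PipelineConfig) -> list[TeamSession]:
    """Read keypoints or tracks, associate identities, clean every track."""
    sessions: list[TeamSession] = []
    if cfg.keypoints_dir:
        for case_id, src in _discover_cases(Path(cfg.keypoints_dir)):
            frames = tio.read_openpose_frames(src, fps=cfg.fps)
            n_det = sum(len(f.detections) for f in frames)
            tracks = associate_detections(
                frames, max_jump=cfg.max_jump, max_gap=cfg.max_gap
            )
            log.info(
                "extract %s: %d frames, %d detections, %d raw tracks",
                case_id, len(frames), n_det, len(tracks),
            )
            min_samples = int(cfg.min_track_s * cfg.fps)
            cleaned = []
            n_dropped = 0
            for t in tracks:
                ct = preprocess_track(
                    t, fps=cfg.fps, confidence_floor=cfg.confidence_floor,
                    k_mad=cfg.k_mad, max_gap=cfg.max_gap,
                )
                if len(ct) < min_samples:
                    n_dropped += 1
                    continue
                log.info(
                    "  track %s: %d -> %d samples after cleaning",
                    t.member_id, len(t), len(ct),
                )
                cleaned.append(ct)
            if n_dropped:
                log.info(
                    "  %d short track(s) (< %gs) dropped as spurious",
                    n_dropped, cfg.min_track_s,
                )
            sessions.append(
                TeamSession(case_id=case_id, fps=cfg.fps, tracks=tuple(cleaned))
            )
    elif cfg.track_csv:
        df = tio.read_track_csv(cfg.track_csv)
        for case_id in sorted(df["case_id"].unique()):
            session = session_from_track_df(df, case_id, fps=cfg.fps)
            cleaned = tuple(
                preprocess_track(
                    t, fps=cfg.fps, confidence_floor=cfg.confidence_floor,
                    k_mad=cfg.k_mad, max_gap=cfg.max_gap,
                )
                if cfg.clean_tracks else t
                for t in session.tracks
            )
            if cfg.clean_tracks:
                min_samples = int(cfg.min_track_s * cfg.fps)
                cleaned = tuple(t for t in cleaned if len(t) >= min_samples)
            log.info("extract %s: %d tracks from CSV", case_id, len(cleaned))
            sessions.append(
                TeamSession(case_id=case_id, fps=cfg.fps, tracks=cleaned)
            )
    else:
        raise ValueError("either keypoints_dir or track_csv must be provided")
    return sessions


def compute_features(sessions: list[TeamSession], cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    for s in sessions:
        fs = compute_feature_set(
            s, window_s=cfg.window_s, n_symbols=cfg.n_symbols, scheme=cfg.scheme
        )
        rows.append(fs.as_row(s.case_id))
        log.info("features %s computed", s.case_id)
    return pd.DataFrame(rows, columns=tio.FEATURE_COLUMNS)


def _icc_to_dict(r) -> dict:
    return {
        "icc": r.icc, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "p_value": r.p_value, "n_cases": r.n_cases, "n_raters": r.n_raters,
    }


def run_stats(
    features: pd.DataFrame,
    ratings: pd.DataFrame,
    covariates: pd.DataFrame | None,
    cfg: PipelineConfig,
) -> dict:
    """Rater aggregation, ICC, normality screen, associations, regressions."""
    averages = average_notss(ratings)
    unmatched_f = sorted(set(features["case_id"]) - set(averages["case_id"]))
    unmatched_r = sorted(set(averages["case_id"]) - set(features["case_id"]))
    if unmatched_f or unmatched_r:
        raise ValueError(
            "case mismatch between features and ratings; "
            f"features-only: {unmatched_f}, ratings-only: {unmatched_r}"
        )

    matrix = notss_case_rater_matrix(ratings)
    icc_all = icc_two_way_mixed_consistency(matrix)
    icc_pairs = {}
    raters = list(matrix.columns)
    for i in range(len(raters)):
        for j in range(i + 1, len(raters)):
            pair = matrix.iloc[:, [i, j]]
            icc_pairs[f"{raters[i]}|{raters[j]}"] = _icc_to_dict(
                icc_two_way_mixed_consistency(pair)
            )
    log.info("ICC(3,k) over %d raters: %.3f", icc_all.n_raters, icc_all.icc)

    feature_cols = tio.FEATURE_COLUMNS[1:]
    normality = {}
    for col in feature_cols:
        vals = features[col].dropna()
        if len(vals) >= 5:
            ks = ks_normality(vals)
            normality[col] = {
                "statistic": ks.statistic, "p_value": ks.p_value,
                "n": ks.n, "degenerate": ks.degenerate,
            }

    assoc = associate(
        features, averages, method=cfg.method,
        feature_columns=feature_cols, bh=cfg.bh,
    )
    for a in assoc:
        log.info(
            "association %s: %s=%.3f p=%.4f%s",
            a.feature, a.method, a.coefficient, a.p_value,
            " *" if a.significant else "",
        )

    regressions = []
    if covariates is not None:
        targets = [
            a.feature for a in assoc
            if (cfg.regress_all or a.significant) and not a.degenerate
        ]
        for feat in targets:
            reg = fit_adjusted_regression(averages, features, feat, covariates)
            regressions.append(reg)
            log.info(
                "regression %s: coef=%.4f adjR2=%.3f",
                feat, reg.params[feat], reg.adj_r2,
            )

    summary = {
        "n_cases": int(len(features)),
        "icc": {"all_raters": _icc_to_dict(icc_all), "rater_pairs": icc_pairs},
        "notss_means": {
            c: float(averages[c].mean())
            for c in averages.columns if c != "case_id"
        },
        "normality": normality,
        "associations": [dataclasses.asdict(a) for a in assoc],
        "regressions": [dataclasses.asdict(r) for r in regressions],
    }
    return {"summary": summary, "averages": averages, "associations": assoc,
            "regressions": regressions}


def _write_stats_outputs(out: Path, stats: dict) -> None:
    assoc_df = pd.DataFrame([dataclasses.asdict(a) for a in stats["associations"]])
    assoc_df.to_csv(out / "associations.csv", index=False, float_format="%.17g")
    reg_rows = []
    for r in stats["regressions"]:
        row = {"feature": r.feature, "r2": r.r2, "adj_r2": r.adj_r2, "n": r.n}
        for k, v in r.params.items():
            key = "intercept" if k == "const" else k
            row[f"coef_{key}"] = v
            row[f"se_{key}"] = r.bse[k]
            row[f"p_{key}"] = r.p_values[k]
        reg_rows.append(row)
    pd.DataFrame(reg_rows).to_csv(
        out / "regressions.csv", index=False, float_format="%.17g"
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(stats["summary"], fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute extract -> features -> stats and write the report bundle.

    Writes ``tracks.csv``, ``features.csv``, ``associations.csv``,
    ``regressions.csv``, ``summary.json`` and ``run.log`` under
    ``cfg.out_dir`` and returns the in-memory results.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, cfg.log_level.upper()))
    try:
        sessions = extract_sessions(cfg)
        tracks_df = pd.concat(
            [session_to_track_df(s) for s in sessions], ignore_index=True
        )
        tio.write_track_csv(tracks_df, out / "tracks.csv")

        features = compute_features(sessions, cfg)
        tio.write_feature_table(features, out / "features.csv")

        result = {"features": features, "sessions": sessions}
        if cfg.ratings_csv:
            ratings = tio.read_ratings_csv(cfg.ratings_csv)
            covariates = (
                tio.read_covariates_csv(cfg.covariates_csv)
                if cfg.covariates_csv else None
            )
            stats = run_stats(features, ratings, covariates, cfg)
            _write_stats_outputs(out, stats)
            result.update(stats)
        return result
    finally:
        log.removeHandler(handler)
        handler.close()
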