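import math

import numpy as np
import pytest

from teammotion.features import (
    acceleration_series,
    compute_feature_set,
    displacement_series,
    shannon_entropy,
    speed_series,
    symbolize_series,
    team_displacement_series,
    team_speed_variability,
    trajectory_total,
    windowed_displacement_entropy,
)
from teammotion.tracking import PersonTrack, TeamSession, TrackWarning

from conftest import random_session, random_track


def _track(frames, xy, member_id="m"):
    xy = np.asarray(xy, float)
    return PersonTrack(member_id, np.asarray(frames), xy,
                       np.full(len(xy), 0.9))


def _session(tracks, fps=30.0, case_id="c", phase=None):
    return TeamSession(case_id=case_id, fps=fps, tracks=tuple(tracks),
                       phase=phase)


class TestDisplacement:
    def test_three_four_five_triangle(self):
        t = _track([0, 1], [[0, 0], [3, 4]])
        assert displacement_series(t).values.tolist() == [5.0]

    def test_constant_track_gives_zeros(self):
        t = _track(range(10), [[7, 7]] * 10)
        assert displacement_series(t).values.tolist() == [0.0] * 9

    def test_gap_spanning_pairs_skipped_not_zero(self):
        t = _track([0, 1, 5, 6], [[0, 0], [1, 0], [2, 0], [4, 0]])
        s = displacement_series(t)
        assert s.frames.tolist() == [0, 5]
        assert s.values.tolist() == [1.0, 2.0]

    def test_matches_naive_loop_oracle(self, rng):
        t = random_track(rng, n=50, gap_prob=0.2)
        s = displacement_series(t)
        expected = {}
        for i in range(1, len(t)):
            if t.frames[i] - t.frames[i - 1] == 1:
                dx = t.xy[i, 0] - t.xy[i - 1, 0]
                dy = t.xy[i, 1] - t.xy[i - 1, 1]
                expected[int(t.frames[i - 1])] = math.sqrt(dx * dx + dy * dy)
        assert s.frames.tolist() == sorted(expected)
        assert np.allclose(s.values, [expected[f] for f in sorted(expected)],
                           rtol=1e-12)

    def test_single_sample_warns_empty(self):
        with pytest.warns(TrackWarning):
            s = displacement_series(_track([0], [[1, 1]]))
        assert len(s) == 0


class TestTrajectory:
    def test_sum_of_displacements(self):
        t = _track([0, 1, 2, 3], [[0, 0], [5, 0], [5, 0], [5, 5]])
        assert trajectory_total(t) == 10.0

    def test_constant_track_zero(self):
        assert trajectory_total(_track(range(5), [[3, 3]] * 5)) == 0.0

    def test_equals_series_sum_on_random_tracks(self, rng):
        for _ in range(5):
            t = random_track(rng, n=40, gap_prob=0.15)
            assert trajectory_total(t) == pytest.approx(
                displacement_series(t).values.sum(), rel=1e-12
            )


class TestSpeed:
    def test_pixels_per_second_arithmetic(self):
        t = _track([0, 1], [[0, 0], [5, 0]])
        assert speed_series(t, fps=30.0).values.tolist() == [150.0]

    def test_gap_pair_uses_elapsed_time(self):
        t = _track([0, 2], [[0, 0], [5, 0]])
        assert speed_series(t, fps=30.0).values.tolist() == [75.0]

    def test_fps_one_equals_displacement_on_gapless_track(self, rng):
        t = random_track(rng, n=30)
        assert np.array_equal(speed_series(t, fps=1.0).values,
                              displacement_series(t).values)


class TestAcceleration:
    def test_constant_speed_zero_acceleration(self):
        from teammotion.features import DisplacementSeries
        s = DisplacementSeries(np.arange(3), [150.0, 150.0, 150.0])
        assert acceleration_series(s).tolist() == [0.0, 0.0]

    def test_signed_differences(self):
        from teammotion.features import DisplacementSeries
        s = DisplacementSeries(np.arange(3), [0.0, 10.0, 5.0])
        assert acceleration_series(s).tolist() == [10.0, -5.0]

    def test_telescoping_sum(self, rng):
        t = random_track(rng, n=60)
        s = speed_series(t, fps=30.0)
        acc = acceleration_series(s)
        assert acc.sum() == pytest.approx(s.values[-1] - s.values[0], abs=1e-9)


class TestTeamSeries:
    def test_mean_of_contributing_members(self):
        a = _track([0, 1], [[0, 0], [2, 0]], "a")
        b = _track([0, 1], [[10, 0], [14, 0]], "b")
        s = team_displacement_series(_session([a, b]))
        assert s.values.tolist() == [3.0]

    def test_single_member_team_identity(self, rng):
        t = random_track(rng, n=25)
        team = team_displacement_series(_session([t]))
        assert np.array_equal(team.values, displacement_series(t).values)

    def test_matches_missingness_aware_mean_oracle(self, rng):
        tracks = [random_track(rng, n=40, gap_prob=0.25, member_id=f"m{i}")
                  for i in range(4)]
        team = team_displacement_series(_session(tracks))
        per_frame = {}
        for t in tracks:
            s = displacement_series(t)
            for f, v in zip(s.frames, s.values):
                per_frame.setdefault(int(f), []).append(v)
        frames = sorted(per_frame)
        assert team.frames.tolist() == frames
        assert np.allclose(team.values,
                           [np.mean(per_frame[f]) for f in frames], rtol=1e-12)


class TestSpeedVariability:
    def test_identical_motion_zero(self, rng):
        t = random_track(rng, n=30)
        clone = PersonTrack("m2", t.frames, t.xy.copy(), t.confidence)
        assert team_speed_variability(_session([t, clone])) == 0.0

    def test_constant_speeds_zero_and_ten(self):
        n = 20
        a = _track(range(n), [[0, 0]] * n, "a")                # speed 0
        xb = np.arange(n) * (10.0 / 30.0)                      # 10 px/s at 30 fps
        b = _track(range(n), np.column_stack([xb, np.zeros(n)]), "b")
        assert team_speed_variability(_session([a, b])) == pytest.approx(5.0)

    def test_matches_two_pass_sd_oracle(self, rng):
        tracks = [random_track(rng, n=50, gap_prob=0.2, member_id=f"m{i}")
                  for i in range(4)]
        session = _session(tracks)
        got = team_speed_variability(session)
        per_frame = {}
        for t in tracks:
            s = speed_series(t, session.fps)
            for f, v in zip(s.frames, s.values):
                per_frame.setdefault(int(f), []).append(v)
        sds = []
        for f, vals in per_frame.items():
            if len(vals) >= 2:
                m = sum(vals) / len(vals)
                sds.append(math.sqrt(sum((v - m) ** 2 for v in vals) / len(vals)))
        assert got == pytest.approx(np.mean(sds), rel=1e-10)

    def test_lone_member_yields_nan_with_warning(self, rng):
        t = random_track(rng, n=10)
        with pytest.warns(TrackWarning):
            assert math.isnan(team_speed_variability(_session([t])))


class TestSymbolize:
    def test_constant_series_all_zero_symbols(self):
        for scheme in ("quantile", "equal_width"):
            assert symbolize_series(np.full(7, 3.3), 4, scheme).tolist() == [0] * 7

    def test_equal_width_midpoint_split(self):
        assert symbolize_series(np.array([1.0, 2, 3, 4]), 2,
                                "equal_width").tolist() == [0, 0, 1, 1]

    def test_value_on_edge_goes_to_higher_bin(self):
        # edges for [0..4] with 2 equal-width bins: 2.0
        assert symbolize_series(np.array([0.0, 2.0, 4.0]), 2,
                                "equal_width").tolist() == [0, 1, 1]

    def test_quantile_bins_balanced(self, rng):
        x = rng.uniform(0, 10, 1000)
        sym = symbolize_series(x, 5, "quantile")
        counts = np.bincount(sym, minlength=5)
        assert counts.max() - counts.min() <= 1

    def test_too_few_symbols_rejected(self):
        with pytest.raises(ValueError):
            symbolize_series(np.arange(4.0), 1, "quantile")


class TestEntropy:
    @pytest.mark.parametrize(
        "symbols,bits",
        [([0, 0, 0, 0], 0.0), ([0, 1, 2, 3], 2.0), ([0, 0, 1, 2], 1.5)],
    )
    def test_known_distributions(self, symbols, bits):
        assert shannon_entropy(np.array(symbols)) == pytest.approx(bits)

    def test_constant_team_series_zero_windowed_entropy(self):
        n = 300
        tracks = [_track(range(n), [[i * 100, 0]] * n, f"m{i}")
                  for i in range(3)]
        s = _session(tracks, fps=1.0)
        assert windowed_displacement_entropy(s, window_s=60) == 0.0

    def test_mean_of_two_window_entropies(self):
        # fps=1, window 4 transitions: first window one symbol (H=0),
        # second window four distinct symbols (H=2); mean = 1
        disp = [0.0, 0.0, 0.0, 0.0, 1.0, 3.0, 5.0, 7.0]
        x = np.concatenate([[0.0], np.cumsum(disp)])
        t = _track(range(9), np.column_stack([x, np.zeros(9)]))
        s = _session([t], fps=1.0)
        got = windowed_displacement_entropy(s, window_s=4, n_symbols=4,
                                            scheme="equal_width")
        assert got == pytest.approx(1.0)

    def test_short_session_falls_back_to_whole_series(self, rng):
        t = random_track(rng, n=20)
        s = _session([t], fps=30.0)
        with pytest.warns(TrackWarning):
            got = windowed_displacement_entropy(s, window_s=60)
        sym = symbolize_series(team_displacement_series(s))
        assert got == pytest.approx(shannon_entropy(sym))

    def test_low_erraticity_sessions_less_entropic(self):
        from teammotion.simulate import SimulationConfig, simulate_team_session
        for seed in range(8):
            lows, highs = [], []
            for eps, out in ((0.05, lows), (0.95, highs)):
                cfg = SimulationConfig(n_cases=3, duration_s=150, seed=seed,
                                       erraticity=eps, missing_rate=0.0,
                                       outlier_rate=0.0)
                for i in range(cfg.n_cases):
                    session, _ = simulate_team_session(cfg, i)
                    out.append(windowed_displacement_entropy(session))
            assert np.mean(lows) < np.mean(highs)


class TestFeatureSet:
    def test_motionless_team_all_zero(self):
        n = 200
        tracks = [_track(range(n), [[100 * i, 50]] * n, f"m{i}")
                  for i in range(2)]
        fs = compute_feature_set(_session(tracks, fps=1.0), window_s=50)
        assert fs.mean_displacement == 0.0
        assert fs.mean_trajectory == 0.0
        assert fs.mean_speed == 0.0
        assert fs.speed_variability == 0.0
        assert fs.mean_abs_acceleration == 0.0
        assert fs.displacement_entropy == 0.0

    def test_single_transition_session_degrades_gracefully(self):
        tracks = [_track([0, 1], [[0, 0], [1, 0]], "a"),
                  _track([0, 1], [[5, 5], [5, 6]], "b")]
        fs = compute_feature_set(_session(tracks, fps=30.0))
        assert math.isnan(fs.mean_abs_acceleration)  # needs >= 2 speeds
        assert not math.isnan(fs.displacement_entropy)  # whole-series fallback

    def test_composition_equals_standalone_operations(self, rng):
        session = random_session(rng, n_members=4, n=400, fps=2.0)
        fs = compute_feature_set(session, window_s=60)
        team = team_displacement_series(session)
        assert fs.mean_displacement == pytest.approx(team.values.mean())
        assert fs.mean_trajectory == pytest.approx(
            np.mean([trajectory_total(t) for t in session.tracks])
        )
        speeds = [speed_series(t, session.fps) for t in session.tracks]
        assert fs.mean_speed == pytest.approx(
            np.mean([s.values.mean() for s in speeds])
        )
        assert fs.mean_abs_acceleration == pytest.approx(
            np.mean([np.abs(acceleration_series(s)).mean() for s in speeds])
        )
        assert fs.speed_variability == pytest.approx(
            team_speed_variability(session)
        )
        assert fs.displacement_entropy == pytest.approx(
            windowed_displacement_entropy(session, window_s=60)
        )

    def test_phase_window_restricts_all_features(self, rng):
        t_full = random_track(rng, n=300, member_id="a")
        u_full = random_track(rng, n=300, member_id="b")
        session = _session([t_full, u_full], fps=1.0, phase=(50, 149))
        direct = _session(
            [t.select((t.frames >= 50) & (t.frames <= 149))
             for t in (t_full, u_full)],
            fps=1.0,
        )
        fs_phase = compute_feature_set(session, window_s=30)
        fs_direct = compute_feature_set(direct, window_s=30)
        assert fs_phase == fs_direct
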