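import numpy as np
import pytest

from teammotion.tracking import PersonTrack, TeamSession


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_track(rng, n=50, member_id="m0", start_frame=0, step_sd=3.0,
                 gap_prob=0.0, max_gap=5):
    """A random-walk track with optional random frame gaps."""
    frames = [start_frame]
    for _ in range(n - 1):
        hop = 1
        if gap_prob and rng.random() < gap_prob:
            hop += rng.integers(1, max_gap + 1)
        frames.append(frames[-1] + hop)
    xy = np.cumsum(rng.normal(0.0, step_sd, (n, 2)), axis=0) + [500.0, 400.0]
    conf = rng.uniform(0.3, 1.0, n)
    return PersonTrack(member_id=member_id, frames=np.array(frames),
                       xy=xy, confidence=conf)


def random_session(rng, n_members=4, n=60, case_id="caseX", fps=30.0,
                   gap_prob=0.0):
    tracks = tuple(
        random_track(rng, n=n, member_id=f"m{i}", gap_prob=gap_prob)
        for i in range(n_members)
    )
    return TeamSession(case_id=case_id, fps=fps, tracks=tracks)


@pytest.fixture
def make_track(rng):
    return lambda **kw: random_track(rng, **kw)


@pytest.fixture
def make_session(rng):
    return lambda **kw: random_session(rng, **kw)
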