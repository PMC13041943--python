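import numpy as np
import pytest

from prophagekit import ScoreTrack, SegmentScores


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(probs, genome_id="g1", window_length=2000, step=1000, start0=0):
    probs = np.asarray(probs, dtype=float)
    starts = start0 + step * np.arange(probs.size)
    return ScoreTrack(
        genome_id=genome_id, window_length=window_length, step=step,
        window_starts=starts, probabilities=probs,
    )


def make_scores(values, genome_id="g1", step=1000, start0=0):
    values = np.asarray(values, dtype=float)
    starts = start0 + step * np.arange(values.size)
    return SegmentScores(
        genome_id=genome_id, step=step, segment_starts=starts, values=values
    )
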