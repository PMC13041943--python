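"""The prophage signal-extraction algorithm."""

import numpy as np
import pytest

from prophagekit import (
    ExtractionConfig,
    SearchGrid,
    ValidationError,
    call_regions,
    collapse_windows,
    extract_prophages,
    normalize_scores,
    smooth_bidirectional_ewm,
    tune_config,
)
from prophagekit.evaluation import evaluate_genome_wide

from conftest import make_scores, make_track


def brute_force_collapse(track):
    """Per-base oracle: average covering windows per base, then per segment."""
    start0 = int(track.window_starts[0])
    span = int(track.window_starts[-1]) + track.window_length - start0
    sums = np.zeros(span)
    counts = np.zeros(span)
    for s, p in zip(track.window_starts, track.probabilities):
        lo = int(s) - start0
        sums[lo : lo + track.window_length] += p
        counts[lo : lo + track.window_length] += 1
    per_base = sums / counts
    return np.array(
        [per_base[i : i + track.step].mean() for i in range(0, span, track.step)]
    )


class TestCollapse:
    def test_two_window_example(self):
        track = make_track([0.9, 0.7])
        seg = collapse_windows(track)
        assert seg.segment_starts.tolist() == [0, 1000, 2000]
        assert seg.values == pytest.approx([0.9, 0.8, 0.7])

    def test_single_window(self):
        seg = collapse_windows(make_track([0.42]))
        assert seg.values == pytest.approx([0.42, 0.42])

    def test_constant_preserved(self):
        seg = collapse_windows(make_track([0.3] * 10))
        assert np.allclose(seg.values, 0.3)

    def test_step_not_dividing_window_raises(self):
        with pytest.raises(ValidationError):
            collapse_windows(make_track([0.5, 0.5], window_length=2000, step=1500))

    def test_matches_per_base_oracle_on_random_tracks(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 30))
            k = int(rng.integers(1, 5))
            step = int(rng.integers(1, 6)) * 100
            track = make_track(
                rng.uniform(size=n), window_length=k * step, step=step,
                start0=int(rng.integers(0, 3)) * step,
            )
            assert collapse_windows(track).values == pytest.approx(
                brute_force_collapse(track)
            )


class TestNormalize:
    def test_constant_zscore_is_zeros(self):
        assert normalize_scores(make_scores([1, 1, 1]), "zscore").values == pytest.approx(
            [0, 0, 0]
        )

    def test_zscore_population_std(self):
        assert normalize_scores(make_scores([0, 1]), "zscore").values == pytest.approx(
            [-1, 1]
        )

    def test_median_subtract(self):
        out = normalize_scores(make_scores([1, 2, 3]), "median_subtract")
        assert out.values == pytest.approx([-1, 0, 1])

    def test_robust_zscore_scale(self):
        out = normalize_scores(make_scores([1.0, 2.0, 3.0, 4.0, 100.0]), "robust_zscore")
        # median 3, MAD 1 -> (v - 3) / 1.4826
        assert out.values[0] == pytest.approx(-2 / 1.4826)

    def test_robust_falls_back_to_zscore_when_mad_zero(self):
        v = [5.0, 5.0, 5.0, 9.0]
        out = normalize_scores(make_scores(v), "robust_zscore")
        assert out.values == pytest.approx(normalize_scores(make_scores(v), "zscore").values)

    def test_none_is_identity(self):
        v = [0.2, 0.9, 0.4]
        assert normalize_scores(make_scores(v), "none").values == pytest.approx(v)


class TestSmoothing:
    def test_span_one_is_identity(self, rng):
        v = rng.uniform(size=20)
        assert smooth_bidirectional_ewm(make_scores(v), 1).values == pytest.approx(v)

    def test_constant_is_fixed_point(self):
        v = [0.7] * 15
        for span in (1, 3, 9):
            assert smooth_bidirectional_ewm(make_scores(v), span).values == pytest.approx(v)

    def test_palindrome_stays_palindrome(self, rng):
        half = rng.uniform(size=10)
        v = np.concatenate([half, half[::-1]])
        out = smooth_bidirectional_ewm(make_scores(v), 5).values
        assert out == pytest.approx(out[::-1])


class TestCallRegions:
    calls = [0, 1, 1, 0, 1, 1, 0]

    def test_gap_one_absorbs_single_gap(self):
        regions = call_regions(make_scores(self.calls), 0.5, max_gap=1, min_length=1000)
        assert [(r.start, r.end) for r in regions] == [(1000, 6000)]

    def test_gap_zero_keeps_two_regions(self):
        regions = call_regions(make_scores(self.calls), 0.5, max_gap=0, min_length=1000)
        assert [(r.start, r.end) for r in regions] == [(1000, 3000), (4000, 6000)]

    def test_min_length_filters_all(self):
        regions = call_regions(make_scores(self.calls), 0.5, max_gap=0, min_length=3000)
        assert regions == []

    def test_region_score_is_mean_of_segments(self):
        scores = make_scores([0.0, 0.8, 0.6, 0.0])
        (r,) = call_regions(scores, 0.5, 0, 1000)
        assert r.score == pytest.approx(0.7)

    def test_idempotent_under_remerge(self, rng):
        for _ in range(50):
            v = (rng.uniform(size=30) > 0.5).astype(float)
            gap = int(rng.integers(0, 4))
            regions = call_regions(make_scores(v), 0.5, gap, 1000)
            # re-threshold a binary indicator rebuilt from the called regions
            indicator = np.zeros(30)
            for r in regions:
                indicator[r.start // 1000 : r.end // 1000] = 1.0
            again = call_regions(make_scores(indicator), 0.5, gap, 1000)
            assert [(r.start, r.end) for r in again] == [
                (r.start, r.end) for r in regions
            ]

    def test_monotone_in_min_length_and_gap(self, rng):
        v = (rng.uniform(size=60) > 0.6).astype(float)
        scores = make_scores(v)
        counts = [
            len(call_regions(scores, 0.5, 1, ml)) for ml in (1000, 4000, 8000, 16000)
        ]
        assert counts == sorted(counts, reverse=True)
        prev_n, prev_cov = None, None
        for gap in (0, 1, 2, 5):
            regs = call_regions(scores, 0.5, gap, 1000)
            n = len(regs)
            cov = sum(r.length for r in regs)
            if prev_n is not None:
                assert n <= prev_n
                assert cov >= prev_cov
            prev_n, prev_cov = n, cov


class TestPipeline:
    def test_recovers_implanted_block(self):
        probs = np.full(100, 0.1)
        probs[40:60] = 0.9
        track = make_track(probs)
        regions = extract_prophages(track, ExtractionConfig())
        assert len(regions) == 1
        r = regions[0]
        assert r.start <= 41_000 and r.end >= 59_000

    def test_all_zero_track_is_empty(self):
        assert extract_prophages(make_track([0.0] * 50), ExtractionConfig()) == []

    def test_min_length_below_step_raises(self):
        with pytest.raises(ValidationError):
            extract_prophages(make_track([0.5] * 5), ExtractionConfig(min_length=10))

    @pytest.mark.parametrize("strategy", ["zscore", "robust_zscore", "median_subtract"])
    def test_shift_invariance(self, strategy, rng):
        from prophagekit import call_regions, normalize_scores, smooth_bidirectional_ewm

        v = rng.uniform(size=80)
        v[20:40] += 0.6
        for shift in (-0.5, 0.3, 2.0):
            def pipeline(values):
                s = make_scores(values)
                s = normalize_scores(s, strategy)
                s = smooth_bidirectional_ewm(s, 5)
                return call_regions(s, 1.0, 1, 4000)

            assert [(r.start, r.end) for r in pipeline(v)] == [
                (r.start, r.end) for r in pipeline(v + shift)
            ]


class TestTune:
    def _toy_data(self):
        probs = np.full(60, 0.1)
        probs[20:35] = 0.9
        track = make_track(probs)
        from prophagekit import Region

        truth = [Region("g1", 20_000, 36_000)]
        return [track], truth

    def test_grid_of_one_returns_it(self):
        tracks, truth = self._toy_data()
        cfg = ExtractionConfig()
        best, table = tune_config(tracks, truth, [cfg])
        assert best == cfg
        assert len(table) == 1

    def test_winner_matches_brute_force_re_evaluation(self):
        tracks, truth = self._toy_data()
        grid = SearchGrid(
            normalizations=("zscore", "none"),
            spans=(1, 3),
            thresholds=(0.5, 1.0),
            max_gaps=(0, 1),
            min_lengths=(4000, 8000),
            thresholds_raw=(0.5, 0.7),
        )
        best, table = tune_config(tracks, truth, grid)
        configs = grid.configs()
        assert len(table) == len(configs)
        lengths = {t.genome_id: t.span_end for t in tracks}
        scored = []
        for i, cfg in enumerate(configs):
            preds = [r for t in tracks for r in extract_prophages(t, cfg)]
            _, macro = evaluate_genome_wide(preds, truth, lengths, tracks[0].step)
            scored.append((macro["mcc"], macro["recall"], -i, cfg))
        assert best == max(scored)[3]

    def test_empty_grid_raises(self):
        tracks, truth = self._toy_data()
        with pytest.raises(ValidationError):
            tune_config(tracks, truth, [])
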