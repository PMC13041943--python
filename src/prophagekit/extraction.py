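"""Prophage signal extraction from per-window score tracks.

Pipeline: collapse 50%-overlapping windows to one score per step-sized
segment, normalize per genome (the baseline level of phage-like signal varies
between genomes), smooth with a bidirectional exponentially weighted mean,
threshold, merge small gaps, and drop short candidates.  A grid search over
the five hyperparameters selects the configuration maximizing a macro-averaged
metric against ground-truth annotations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Region, ScoreTrack, SegmentScores
from .errors import ValidationError

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("none", "zscore", "robust_zscore", "median_subtract")

#: Consistency factor making the MAD estimate the standard deviation under
#: a normal model.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class ExtractionConfig:
    """The five signal-extraction hyperparameters.

    threshold applies on the normalized scale (sigma units for zscore /
    robust_zscore, probability units for none); max_gap and smoothing_span
    are in segments; min_length is in nucleotides.
    """

    normalization: str = "zscore"
    smoothing_span: int = 5
    threshold: float = 1.0
    max_gap: int = 2
    min_length: int = 8000

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ValidationError(
                f"normalization must be one of {NORMALIZATIONS}, "
                f"got {self.normalization!r}"
            )
        if self.smoothing_span < 1:
            raise ValidationError("smoothing_span must be >= 1")
        if self.max_gap < 0:
            raise ValidationError("max_gap must be >= 0")
        if self.min_length < 1:
            raise ValidationError("min_length must be >= 1")


@dataclass
class SearchGrid:
    """Candidate value lists for each ExtractionConfig field.

    Normalized strategies threshold in sigma units while raw probabilities
    threshold in [0, 1], so a separate threshold list applies when
    normalization is "none".
    """

    normalizations: Sequence[str] = ("zscore", "robust_zscore", "median_subtract", "none")
    spans: Sequence[int] = (1, 3, 5, 9, 15)
    thresholds: Sequence[float] = tuple(np.arange(0.5, 2.01, 0.25))
    max_gaps: Sequence[int] = (0, 1, 2, 3)
    min_lengths: Sequence[int] = (4000, 8000, 10000, 15000)
    thresholds_raw: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9)

    def configs(self) -> list[ExtractionConfig]:
        """Enumerate the full grid in deterministic order."""
        out = []
        for norm in self.normalizations:
            thr_list = self.thresholds_raw if norm == "none" else self.thresholds
            for span, thr, gap, mlen in itertools.product(
                self.spans, thr_list, self.max_gaps, self.min_lengths
            ):
                out.append(ExtractionConfig(norm, span, float(thr), gap, mlen))
        return out

    @property
    def size(self) -> int:
        return len(self.configs())


def collapse_windows(track: ScoreTrack) -> SegmentScores:
    """Collapse overlapping windows into one score per step-sized segment.

    The score of a segment is the arithmetic mean of the probabilities of all
    windows covering it; edge segments covered by a single window inherit its
    probability.  With 50% overlap this coincides with majority voting of
    binary window calls except at ties, which the downstream ``>= threshold``
    rule resolves toward phage.
    """
    if track.window_length % track.step != 0:
        raise ValidationError(
            f"track {track.genome_id}: step {track.step} does not divide "
            f"window_length {track.window_length}"
        )
    k = track.window_length // track.step
    probs = track.probabilities
    n = probs.size
    ones = np.ones(k)
    sums = np.convolve(probs, ones)  # length n + k - 1
    counts = np.convolve(np.ones(n), ones)
    values = sums / counts
    starts = int(track.window_starts[0]) + track.step * np.arange(n + k - 1)
    return SegmentScores(
        genome_id=track.genome_id, step=track.step,
        segment_starts=starts, values=values,
    )


def normalize_scores(scores: SegmentScores, strategy: str) -> SegmentScores:
    """Normalize collapsed scores per genome.

    zscore: (v - mean) / population std (all-equal input -> zeros);
    robust_zscore: (v - median) / (1.4826 * MAD), falling back to zscore when
    MAD = 0 (and to zeros when the std is also 0); median_subtract: v - median;
    none: identity.
    """
    v = scores.values
    if v.size < 1:
        raise ValidationError("normalize_scores requires >= 1 value")
    if strategy == "none":
        out = v.copy()
    elif strategy == "zscore":
        sd = float(np.std(v))
        out = np.zeros_like(v) if sd == 0 else (v - np.mean(v)) / sd
    elif strategy == "robust_zscore":
        med = float(np.median(v))
        mad = float(np.median(np.abs(v - med)))
        if mad == 0:
            return normalize_scores(scores, "zscore")
        out = (v - med) / (MAD_SCALE * mad)
    elif strategy == "median_subtract":
        out = v - float(np.median(v))
    else:
        raise ValidationError(f"unknown normalization strategy {strategy!r}")
    return SegmentScores(scores.genome_id, scores.step, scores.segment_starts.copy(), out)


def smooth_bidirectional_ewm(scores: SegmentScores, span: int) -> SegmentScores:
    """Bidirectional exponentially weighted mean smoothing.

    alpha = 2 / (span + 1); the forward recursion f_i = a*v_i + (1-a)*f_{i-1}
    is averaged elementwise with the same recursion run on the reversed
    series, making the filter symmetric.  span = 1 (alpha = 1) is the
    identity.
    """
    if span < 1:
        raise ValidationError("span must be >= 1")
    s = pd.Series(scores.values)
    fwd = s.ewm(span=span, adjust=False).mean().to_numpy()
    bwd = s[::-1].ewm(span=span, adjust=False).mean().to_numpy()[::-1]
    out = (fwd + bwd) / 2.0
    return SegmentScores(scores.genome_id, scores.step, scores.segment_starts.copy(), out)


def call_regions(
    scores: SegmentScores,
    threshold: float,
    max_gap: int,
    min_length: int,
) -> list[Region]:
    """Threshold, merge small gaps, and length-filter into prophage regions.

    Segments with value >= threshold are positive; maximal positive runs
    separated by <= max_gap negative segments merge into one region (the gap
    segments are absorbed); regions shorter than min_length nt are dropped.
    A region's score is the mean value of its segments (gaps included).
    """
    pos = scores.values >= threshold
    starts = scores.segment_starts
    step = scores.step
    # indices of maximal positive runs
    runs: list[tuple[int, int]] = []  # [first, last] inclusive segment indices
    i = 0
    n = pos.size
    while i < n:
        if pos[i]:
            j = i
            while j + 1 < n and pos[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge runs separated by <= max_gap negatives
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= max_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    regions: list[Region] = []
    for first, last in merged:
        start = int(starts[first])
        end = int(starts[last]) + step
        if end - start < min_length:
            continue
        score = float(np.mean(scores.values[first : last + 1]))
        regions.append(Region(scores.genome_id, start, end, score=score))
    return regions


def extract_prophages(track: ScoreTrack, config: ExtractionConfig) -> list[Region]:
    """Run the full extraction pipeline on one genome's score track."""
    if config.min_length < track.step:
        raise ValidationError(
            f"min_length {config.min_length} < track step {track.step}"
        )
    collapsed = collapse_windows(track)
    logger.debug(
        "genome %s: collapsed %d segments (mean %.4f, median %.4f, std %.4f)",
        track.genome_id, collapsed.values.size,
        float(np.mean(collapsed.values)), float(np.median(collapsed.values)),
        float(np.std(collapsed.values)),
    )
    normalized = normalize_scores(collapsed, config.normalization)
    smoothed = smooth_bidirectional_ewm(normalized, config.smoothing_span)
    return call_regions(smoothed, config.threshold, config.max_gap, config.min_length)


def tune_config(
    tracks: Sequence[ScoreTrack],
    truth: Sequence[Region],
    grid: SearchGrid | Sequence[ExtractionConfig],
    metric: str = "mcc",
    genome_lengths: Mapping[str, int] | None = None,
    min_overlap_frac: float = 0.5,
) -> tuple[ExtractionConfig, pd.DataFrame]:
    """Exhaustive grid search maximizing a macro-averaged region-level metric.

    Ties break by higher macro recall, then by smaller grid index.  Returns
    the winning configuration and the full score table.
    """
    from .evaluation import evaluate_genome_wide

    configs = grid.configs() if isinstance(grid, SearchGrid) else list(grid)
    if not configs:
        raise ValidationError("empty search grid")
    if not tracks:
        raise ValidationError("no score tracks supplied")
    logger.info("grid search over %d configurations", len(configs))
    if genome_lengths is None:
        genome_lengths = {t.genome_id: t.span_end for t in tracks}
    step = tracks[0].step
    rows = []
    best: tuple[float, float, int] | None = None
    best_config = configs[0]
    for idx, cfg in enumerate(configs):
        preds: list[Region] = []
        for t in tracks:
            preds.extend(extract_prophages(t, cfg))
        _, macro = evaluate_genome_wide(
            preds, truth, genome_lengths, step, min_overlap_frac
        )
        key = (macro[metric], macro["recall"], -idx)
        if best is None or key > best:
            best = key
            best_config = cfg
        rows.append(
            {
                "normalization": cfg.normalization,
                "smoothing_span": cfg.smoothing_span,
                "threshold": cfg.threshold,
                "max_gap": cfg.max_gap,
                "min_length": cfg.min_length,
                **{k: macro[k] for k in ("mcc", "recall", "fpr", "precision", "f1")},
            }
        )
    return best_config, pd.DataFrame(rows)
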