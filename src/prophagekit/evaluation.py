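"""Classification and genome-wide detection metrics.

Region-level evaluation is realized on a step-sized grid: a grid segment is
positive when at least ``min_overlap_frac`` of its bases fall inside the
union of regions.  Metrics are computed per genome from the resulting
confusion counts and macro-averaged (unweighted mean over genomes); genomes
without any true prophage are excluded from the recall/FNR averages, where
those ratios are undefined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import ConfusionCounts, Region, merge_intervals
from .errors import ValidationError


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass(frozen=True)
class RateMetrics:
    fpr: float
    fnr: float
    recall: float
    precision: float
    specificity: float
    f1: float


def _ratio(num: int, den: int) -> float:
    return 0.0 if den == 0 else num / den


def rate_metrics(counts: ConfusionCounts) -> RateMetrics:
    """FPR, FNR, recall, precision, specificity and F1 (0/0 -> 0)."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    recall = _ratio(tp, tp + fn)
    precision = _ratio(tp, tp + fp)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return RateMetrics(
        fpr=_ratio(fp, fp + tn),
        fnr=_ratio(fn, fn + tp),
        recall=recall,
        precision=precision,
        specificity=_ratio(tn, tn + fp),
        f1=f1,
    )


@dataclass
class GenomeEval:
    """Per-genome confusion counts and derived metrics."""

    genome_id: str
    counts: ConfusionCounts
    mcc: float
    fpr: float
    fnr: float
    recall: float
    precision: float
    specificity: float
    f1: float
    has_truth: bool


@dataclass
class CategorySensitivity:
    """Detection sensitivity for one phage functional (PHROG) category."""

    category: str
    n_genes: int
    n_detected: int

    @property
    def sensitivity(self) -> float:
        return _ratio(self.n_detected, self.n_genes)


def label_grid(
    genome_length: int,
    step: int,
    regions: Sequence[Region],
    min_overlap_frac: float = 0.5,
) -> np.ndarray:
    """Tile the genome with step-sized segments and label each one.

    A segment is positive iff at least min_overlap_frac of its bases lie
    inside the union of the regions.  Regions exceeding the genome bounds are
    clipped with a warning.
    """
    if step <= 0:
        raise ValidationError("step must be positive")
    n_seg = (genome_length + step - 1) // step
    coverage = np.zeros(n_seg, dtype=np.int64)
    n_clipped = sum(1 for r in regions if r.end > genome_length)
    if n_clipped:
        warnings.warn(
            f"{n_clipped} region(s) exceed genome bounds; clipped",
            stacklevel=2,
        )
    bounded = [
        Region(r.genome_id, r.start, min(r.end, genome_length))
        for r in regions
        if r.start < genome_length
    ]
    for r in merge_intervals(bounded):
        first = r.start // step
        last = (r.end - 1) // step
        for i in range(first, last + 1):
            seg_start, seg_end = i * step, min((i + 1) * step, genome_length)
            coverage[i] += max(0, min(r.end, seg_end) - max(r.start, seg_start))
    seg_sizes = np.full(n_seg, step, dtype=np.int64)
    if genome_length % step:
        seg_sizes[-1] = genome_length % step
    return coverage >= min_overlap_frac * seg_sizes


def _genome_eval(gid: str, counts: ConfusionCounts, has_truth: bool) -> GenomeEval:
    rm = rate_metrics(counts)
    return GenomeEval(
        genome_id=gid, counts=counts, mcc=mcc(counts),
        fpr=rm.fpr, fnr=rm.fnr, recall=rm.recall, precision=rm.precision,
        specificity=rm.specificity, f1=rm.f1, has_truth=has_truth,
    )


def evaluate_genome_wide(
    predictions: Sequence[Region],
    truth: Sequence[Region],
    genome_lengths: Mapping[str, int],
    step: int,
    min_overlap_frac: float = 0.5,
) -> tuple[list[GenomeEval], dict[str, float]]:
    """Region-level evaluation per genome plus an unweighted macro summary.

    Every genome in ``genome_lengths`` contributes to the FPR, specificity,
    precision, F1 and MCC means; genomes with no true region are excluded
    from the recall and FNR means (undefined ratios).
    """
    known = set(genome_lengths)
    unknown = sorted({r.genome_id for r in list(predictions) + list(truth)} - known)
    if unknown:
        raise ValidationError(f"regions reference genomes of unknown length: {unknown}")
    preds_by: dict[str, list[Region]] = {}
    truth_by: dict[str, list[Region]] = {}
    for r in predictions:
        preds_by.setdefault(r.genome_id, []).append(r)
    for r in truth:
        truth_by.setdefault(r.genome_id, []).append(r)
    evals: list[GenomeEval] = []
    for gid in sorted(known):
        length = genome_lengths[gid]
        t = label_grid(length, step, truth_by.get(gid, ()), min_overlap_frac)
        p = label_grid(length, step, preds_by.get(gid, ()), min_overlap_frac)
        counts = ConfusionCounts(
            tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
            fn=int(np.sum(~p & t)), tn=int(np.sum(~p & ~t)),
        )
        evals.append(_genome_eval(gid, counts, has_truth=bool(t.any())))
    with_truth = [e for e in evals if e.has_truth]
    def _mean(attr: str, subset: Sequence[GenomeEval]) -> float:
        return float(np.mean([getattr(e, attr) for e in subset])) if subset else 0.0
    macro = {
        "mcc": _mean("mcc", evals),
        "fpr": _mean("fpr", evals),
        "specificity": _mean("specificity", evals),
        "precision": _mean("precision", evals),
        "f1": _mean("f1", evals),
        "recall": _mean("recall", with_truth),
        "fnr": _mean("fnr", with_truth),
        "n_genomes": float(len(evals)),
        "n_genomes_with_truth": float(len(with_truth)),
    }
    return evals, macro


def phrog_sensitivity(
    categories: Sequence[str],
    predicted_phage: Sequence[bool],
) -> list[CategorySensitivity]:
    """Per-category detection sensitivity over CDS-level predictions.

    ``categories[i]`` is the PHROG category of gene i and
    ``predicted_phage[i]`` whether the model called it phage.  Categories are
    returned ordered by descending sensitivity (then name, for stability).
    """
    if len(categories) != len(predicted_phage):
        raise ValidationError("categories and predictions differ in length")
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for cat, pred in zip(categories, predicted_phage):
        totals[cat] = totals.get(cat, 0) + 1
        hits[cat] = hits.get(cat, 0) + bool(pred)
    out = [CategorySensitivity(c, totals[c], hits[c]) for c in totals]
    out.sort(key=lambda cs: (-cs.sensitivity, cs.category))
    return out


def gc_bias_check(
    predicted_labels: Sequence[int],
    true_labels: Sequence[int],
) -> float:
    """MCC of predictions on a GC-preserving shuffled control set.

    On shuffled sequences carrying no genomic information beyond composition,
    an unbiased model scores 0; a positive MCC flags compositional bias.
    """
    y_pred = np.asarray(predicted_labels, dtype=int)
    y_true = np.asarray(true_labels, dtype=int)
    if y_pred.shape != y_true.shape or y_pred.size == 0:
        raise ValidationError("label vectors must be non-empty and equal length")
    n_pos = int(np.sum(y_true == 1))
    if n_pos * 2 != y_true.size:
        warnings.warn(
            "control labels are not balanced 1:1; MCC still computed",
            stacklevel=2,
        )
    counts = ConfusionCounts(
        tp=int(np.sum((y_pred == 1) & (y_true == 1))),
        fp=int(np.sum((y_pred == 1) & (y_true == 0))),
        fn=int(np.sum((y_pred == 0) & (y_true == 1))),
        tn=int(np.sum((y_pred == 0) & (y_true == 0))),
    )
    return mcc(counts)
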