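"""Multi-model consensus screening of non-ground-truth predictions.

Predictions that overlap no annotated prophage are pooled across models,
merged transitively into consensus candidate regions with per-model support
counts, flagged as novel when missed by every reference tool, and classified
by gene-content rules (structural-gene fraction, head/tail presence,
integration and conjugation machinery).  The rule set formalizes a manual
review protocol; classifications are heuristics over annotation evidence,
not sequence-level calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import Region
from .errors import FormatError, ValidationError


class Classification(str, Enum):
    LIKELY_PHAGE = "likely_phage"
    POSSIBLE_PHAGE = "possible_phage"
    WEAK_SIGNAL = "weak_signal"
    GENOMIC_ISLAND_ICE = "genomic_island_ice"
    GENOMIC_ISLAND = "genomic_island"
    UNLIKELY_PHAGE = "unlikely_phage"
    UNCLASSIFIED = "unclassified"


@dataclass
class CandidateRegion:
    """A consensus interval supported by one or more models."""

    region: Region
    supporting_models: tuple[str, ...]
    novel: bool | None = None
    classification: Classification | None = None

    def __post_init__(self) -> None:
        if len(self.supporting_models) < 1:
            raise ValidationError("a candidate needs >= 1 supporting model")

    @property
    def support(self) -> int:
        return len(set(self.supporting_models))


@dataclass(frozen=True)
class GeneContent:
    """Annotation evidence for one candidate region.

    n_structural counts head & packaging, tail, and connector genes — the
    hallmark structural categories of an intact phage.
    """

    n_genes: int
    n_structural: int
    has_head_or_tail: bool = False
    has_integrase_or_excision: bool = False
    has_lysis: bool = False
    has_conjugation: bool = False

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_structural < 0:
            raise ValidationError("gene counts must be non-negative")
        if self.n_structural > self.n_genes:
            raise ValidationError("n_structural cannot exceed n_genes")


def _overlaps_any(region: Region, others: Sequence[Region]) -> bool:
    return any(region.overlaps(o) for o in others)


def subtract_truth(
    predictions: Sequence[Region], truth: Sequence[Region]
) -> list[Region]:
    """Predictions with zero base overlap with any truth region.

    Partially overlapping predictions are dropped entirely, not trimmed;
    half-open touching intervals do not overlap.
    """
    truth_by: dict[str, list[Region]] = {}
    for t in truth:
        truth_by.setdefault(t.genome_id, []).append(t)
    return [
        p for p in predictions
        if not _overlaps_any(p, truth_by.get(p.genome_id, ()))
    ]


def merge_consensus(
    per_model_predictions: Mapping[str, Sequence[Region]],
    min_support: int = 2,
) -> list[CandidateRegion]:
    """Merge predictions across models into consensus candidates.

    Regions sharing >= 1 base merge transitively into maximal intervals;
    support is the number of distinct models contributing at least one
    region.  Candidates below min_support are removed.  The result is
    independent of model iteration order.
    """
    if not per_model_predictions:
        raise ValidationError("at least one model's predictions are required")
    tagged: dict[str, list[tuple[int, int, str]]] = {}
    for model in sorted(per_model_predictions):
        for r in per_model_predictions[model]:
            tagged.setdefault(r.genome_id, []).append((r.start, r.end, model))
    out: list[CandidateRegion] = []
    for gid in sorted(tagged):
        items = sorted(tagged[gid])
        cur_start, cur_end = items[0][0], items[0][1]
        cur_models = {items[0][2]}
        for start, end, model in items[1:]:
            if start < cur_end:  # >= 1 shared base
                cur_end = max(cur_end, end)
                cur_models.add(model)
            else:
                out.append(
                    CandidateRegion(
                        Region(gid, cur_start, cur_end),
                        tuple(sorted(cur_models)),
                    )
                )
                cur_start, cur_end, cur_models = start, end, {model}
        out.append(
            CandidateRegion(Region(gid, cur_start, cur_end), tuple(sorted(cur_models)))
        )
    return [c for c in out if c.support >= min_support]


def flag_novel(
    candidates: Sequence[CandidateRegion],
    reference_calls: Mapping[str, Sequence[Region]],
) -> list[CandidateRegion]:
    """Mark candidates missed by every reference tool as novel."""
    all_refs: dict[str, list[Region]] = {}
    for tool in reference_calls:
        for r in reference_calls[tool]:
            all_refs.setdefault(r.genome_id, []).append(r)
    out = []
    for c in candidates:
        novel = not _overlaps_any(c.region, all_refs.get(c.region.genome_id, ()))
        out.append(
            CandidateRegion(c.region, c.supporting_models, novel=novel,
                            classification=c.classification)
        )
    return out


def classify_candidate(genes: GeneContent) -> Classification:
    """Gene-content rule classification of a candidate region.

    likely_phage: >= 10% structural genes including head/tail evidence;
    weak_signal: only 1-2 structural genes, consistent with a degraded
    prophage; possible_phage: 5-10% structural (half-open band [0.05, 0.10));
    genomic_island_ice / genomic_island: integration machinery with / without
    conjugation machinery; otherwise unlikely_phage.  The 1-2-structural-gene
    rule takes precedence over the percentage band.
    """
    if genes.n_genes == 0:
        warnings.warn("candidate with zero genes cannot be classified", stacklevel=2)
        return Classification.UNCLASSIFIED
    frac = genes.n_structural / genes.n_genes
    if frac >= 0.10 and genes.has_head_or_tail:
        return Classification.LIKELY_PHAGE
    if genes.n_structural in (1, 2):
        return Classification.WEAK_SIGNAL
    if 0.05 <= frac < 0.10:
        return Classification.POSSIBLE_PHAGE
    if genes.has_integrase_or_excision and genes.has_conjugation:
        return Classification.GENOMIC_ISLAND_ICE
    if genes.has_integrase_or_excision:
        return Classification.GENOMIC_ISLAND
    return Classification.UNLIKELY_PHAGE


def classify_candidates(
    candidates: Sequence[CandidateRegion],
    gene_content: Mapping[str, GeneContent] | Sequence[GeneContent],
) -> list[CandidateRegion]:
    """Attach classifications; gene content keyed by candidate index or id."""
    if isinstance(gene_content, Mapping):
        contents = [
            gene_content[f"candidate_{i}"] for i in range(len(candidates))
        ]
    else:
        contents = list(gene_content)
    if len(contents) != len(candidates):
        raise ValidationError("one gene-content record per candidate is required")
    return [
        CandidateRegion(
            c.region, c.supporting_models, novel=c.novel,
            classification=classify_candidate(g),
        )
        for c, g in zip(candidates, contents)
    ]


GENE_CONTENT_COLUMNS = [
    "candidate_id", "n_genes", "n_structural", "has_head_or_tail",
    "has_integrase", "has_lysis", "has_conjugation",
]


def read_gene_content(path: str | Path) -> dict[str, GeneContent]:
    """Read a gene-content TSV keyed by candidate id."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(GENE_CONTENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    def _bool(v: object) -> bool:
        return str(v).strip().lower() in ("1", "true", "yes")
    out: dict[str, GeneContent] = {}
    for r in df.itertuples(index=False):
        d = r._asdict()
        out[str(d["candidate_id"])] = GeneContent(
            n_genes=int(d["n_genes"]),
            n_structural=int(d["n_structural"]),
            has_head_or_tail=_bool(d["has_head_or_tail"]),
            has_integrase_or_excision=_bool(d["has_integrase"]),
            has_lysis=_bool(d["has_lysis"]),
            has_conjugation=_bool(d["has_conjugation"]),
        )
    return out


def write_gene_content(content: Mapping[str, GeneContent], path: str | Path) -> None:
    rows = [
        (
            cid, g.n_genes, g.n_structural, int(g.has_head_or_tail),
            int(g.has_integrase_or_excision), int(g.has_lysis),
            int(g.has_conjugation),
        )
        for cid, g in content.items()
    ]
    pd.DataFrame(rows, columns=GENE_CONTENT_COLUMNS).to_csv(path, sep="\t", index=False)
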