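"""Benchmark dataset construction.

Builds a balanced phage/bacteria segment dataset with contamination
filtering, fixed-length subsampling, cluster-exclusive train/dev/test splits,
and the three control variants (GC-preserving shuffle, single-class, and
CDS-level functional-category sets).  Clusters are ANI clusters for phages
and genera for bacteria, consumed verbatim from metadata; keeping every
segment of a cluster in a single partition prevents similarity-driven
leakage between splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GenomeRecord, SeqClass
from .errors import FormatError, ValidationError

STANDARD_SEGMENT_LENGTHS = (2000, 4000, 8000)

#: attempts per requested segment before downgrading the count
PLACEMENT_ATTEMPT_FACTOR = 1000


@dataclass
class Segment:
    """A fixed- or CDS-length training sample cut from one genome."""

    genome_id: str
    start: int
    end: int
    label: SeqClass
    cluster_id: str
    split: str = "unassigned"
    category: str | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"segment {self.genome_id}:{self.start}-{self.end}: invalid interval"
            )
        if isinstance(self.label, str):
            self.label = SeqClass(self.label)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a tabular alignment report (outfmt-6-like)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValidationError("percent identity must lie in [0, 100]")
        if self.alignment_length < 1:
            raise ValidationError("alignment length must be >= 1")


@dataclass(frozen=True)
class SplitRatios:
    train: float = 0.8
    dev: float = 0.1
    test: float = 0.1

    def __post_init__(self) -> None:
        if min(self.train, self.dev, self.test) < 0:
            raise ValidationError("split ratios must be non-negative")
        if abs(self.train + self.dev + self.test - 1.0) > 1e-9:
            raise ValidationError("split ratios must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {"train": self.train, "dev": self.dev, "test": self.test}


def read_alignment_hits(path: str | Path) -> list[AlignmentHit]:
    """Read BLAST tabular output; only columns 1-4 are consumed."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 4:
        raise FormatError(f"{path}: expected >= 4 columns (qseqid sseqid pident length)")
    return [
        AlignmentHit(str(r[0]), str(r[1]), float(r[2]), int(r[3]))
        for r in df.itertuples(index=False)
    ]


def filter_contaminated(
    bacteria: Sequence[GenomeRecord],
    hits: Iterable[AlignmentHit],
    min_length: int = 200,
    min_identity: float = 90.0,
) -> tuple[list[GenomeRecord], list[str]]:
    """Exclude bacterial genomes with phage-similar alignments.

    A genome is excluded iff it participates (as query or subject) in at
    least one hit with alignment_length >= min_length and percent_identity
    >= min_identity.  Hits that reference no known bacterial genome are
    ignored with a warning count.
    """
    ids = {g.genome_id for g in bacteria}
    excluded: set[str] = set()
    n_unknown = 0
    for hit in hits:
        involved = {hit.query_id, hit.subject_id} & ids
        if not involved:
            n_unknown += 1
            continue
        if hit.alignment_length >= min_length and hit.percent_identity >= min_identity:
            excluded.update(involved)
    if n_unknown:
        warnings.warn(
            f"{n_unknown} hit(s) referenced no known bacterial genome; ignored",
            stacklevel=2,
        )
    kept = [g for g in bacteria if g.genome_id not in excluded]
    return kept, sorted(excluded)


def _place_nonoverlapping(
    length: int,
    seg_len: int,
    count: int,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]] | None = None,
) -> list[int]:
    """Place ``count`` non-overlapping seg_len intervals uniformly at random.

    Rejection sampling with a bounded attempt budget; any shortfall is then
    filled deterministically from the remaining free gaps (left to right), so
    the returned count is the maximum feasible up to ``count``.
    """
    placed: list[tuple[int, int]] = list(occupied or [])
    starts: list[int] = []
    attempts = 0
    budget = PLACEMENT_ATTEMPT_FACTOR * max(count, 1)
    while len(starts) < count and attempts < budget:
        attempts += 1
        s = int(rng.integers(0, length - seg_len + 1))
        if all(s + seg_len <= a or s >= b for a, b in placed):
            placed.append((s, s + seg_len))
            starts.append(s)
    if len(starts) < count:
        # deterministic fill from free gaps
        placed.sort()
        gaps = []
        prev = 0
        for a, b in placed:
            if a - prev >= seg_len:
                gaps.append((prev, a))
            prev = max(prev, b)
        if length - prev >= seg_len:
            gaps.append((prev, length))
        for a, b in gaps:
            s = a
            while s + seg_len <= b and len(starts) < count:
                starts.append(s)
                s += seg_len
    return sorted(starts)


def sample_segments(
    genome: GenomeRecord,
    seg_len: int,
    rate_bp: int = 10_000,
    seed: int = 0,
) -> list[Segment]:
    """Sample non-overlapping fixed-length segments from one genome.

    The target count is one segment per ``rate_bp`` of genome
    (floor(length / rate_bp)) with a minimum of one; if non-overlapping
    placement cannot reach that count the maximum feasible count is returned
    with a warning.  Genomes shorter than seg_len are skipped with a warning.
    """
    if genome.length_nt < seg_len:
        warnings.warn(
            f"genome {genome.genome_id} shorter than segment length "
            f"{seg_len}; skipped",
            stacklevel=2,
        )
        return []
    count = max(1, genome.length_nt // rate_bp)
    rng = np.random.default_rng(seed)
    starts = _place_nonoverlapping(genome.length_nt, seg_len, count, rng)
    if len(starts) < count:
        warnings.warn(
            f"genome {genome.genome_id}: placed {len(starts)}/{count} segments",
            stacklevel=2,
        )
    return [
        Segment(
            genome_id=genome.genome_id,
            start=s,
            end=s + seg_len,
            label=genome.seq_class,
            cluster_id=genome.cluster_id,
            sequence=genome.sequence[s : s + seg_len],
        )
        for s in starts
    ]


def balance_classes(
    phage_segments: Sequence[Segment],
    bacteria: Sequence[GenomeRecord],
    seg_len: int,
    seed: int = 0,
) -> list[Segment]:
    """Sample bacterial segments to a 1:1 ratio with the phage segments.

    Segments are allocated round-robin across genomes (uniform per genome up
    to the remainder), skipping genomes at capacity, then placed
    non-overlapping within each genome.
    """
    n_target = len(phage_segments)
    if n_target == 0:
        return []
    rng = np.random.default_rng(seed)
    genomes = [g for g in bacteria if g.length_nt >= seg_len]
    order = list(rng.permutation(len(genomes)))
    capacity = {g.genome_id: g.length_nt // seg_len for g in genomes}
    quota: dict[str, int] = {g.genome_id: 0 for g in genomes}
    assigned = 0
    while assigned < n_target:
        progress = False
        for idx in order:
            gid = genomes[idx].genome_id
            if quota[gid] < capacity[gid]:
                quota[gid] += 1
                assigned += 1
                progress = True
                if assigned == n_target:
                    break
        if not progress:
            raise ValidationError(
                f"cannot reach 1:1 balance: need {n_target} bacterial segments, "
                f"capacity is {assigned}"
            )
    out: list[Segment] = []
    for g in genomes:
        k = quota[g.genome_id]
        if k == 0:
            continue
        starts = _place_nonoverlapping(
            g.length_nt, seg_len, k, np.random.default_rng(rng.integers(2**31))
        )
        if len(starts) < k:
            raise ValidationError(
                f"genome {g.genome_id}: could not place {k} non-overlapping segments"
            )
        for s in starts:
            out.append(
                Segment(
                    genome_id=g.genome_id, start=s, end=s + seg_len,
                    label=SeqClass.BACTERIA, cluster_id=g.cluster_id,
                    sequence=g.sequence[s : s + seg_len],
                )
            )
    return out


def split_by_cluster(
    segments: Sequence[Segment],
    ratios: SplitRatios = SplitRatios(),
    seed: int = 0,
) -> list[Segment]:
    """Assign splits so that no cluster straddles partitions.

    Each class is split independently.  Clusters are processed largest first
    (by segment count, ties randomized by seed) and greedily assigned to the
    split with the largest remaining deficit relative to the target ratios.
    """
    by_class: dict[SeqClass, list[Segment]] = {}
    for s in segments:
        if not s.cluster_id:
            raise ValidationError(f"segment in genome {s.genome_id} lacks a cluster_id")
        by_class.setdefault(s.label, []).append(s)
    rng = np.random.default_rng(seed)
    split_names = ("train", "dev", "test")
    targets = ratios.as_dict()
    assignment: dict[tuple[SeqClass, str], str] = {}
    for klass in sorted(by_class, key=lambda k: k.value):
        segs = by_class[klass]
        sizes: dict[str, int] = {}
        for s in segs:
            sizes[s.cluster_id] = sizes.get(s.cluster_id, 0) + 1
        if len(sizes) < 3:
            raise ValidationError(
                f"class {klass.value}: {len(sizes)} cluster(s); need >= 3 to "
                "populate train/dev/test"
            )
        clusters = list(sizes)
        rng.shuffle(clusters)
        clusters.sort(key=lambda c: -sizes[c])  # stable: ties stay shuffled
        total = len(segs)
        current = {name: 0 for name in split_names}
        assigned_clusters = {name: 0 for name in split_names}
        for pos, c in enumerate(clusters):
            deficits = {
                name: targets[name] * total - current[name] for name in split_names
            }
            empty = [n for n in split_names if assigned_clusters[n] == 0]
            remaining = len(clusters) - pos
            if remaining <= len(empty):
                # every split must end up populated
                chosen = max(empty, key=lambda name: deficits[name])
            else:
                chosen = max(split_names, key=lambda name: deficits[name])
            assignment[(klass, c)] = chosen
            current[chosen] += sizes[c]
            assigned_clusters[chosen] += 1
    return [
        replace(s, split=assignment[(s.label, s.cluster_id)]) for s in segments
    ]


def shuffle_gc_control(sequence: str, seed: int = 0) -> str:
    """Uniform random permutation of a sequence's characters.

    Preserves length and base composition (hence GC content) while
    destroying all higher-order sequence patterns.
    """
    if not sequence:
        raise ValidationError("cannot shuffle an empty sequence")
    rng = np.random.default_rng(seed)
    chars = np.array(list(sequence))
    return "".join(rng.permutation(chars))


def build_class_control(
    genomes: Sequence[GenomeRecord],
    klass: SeqClass | str,
    n_genomes: int,
    seg_len: int,
    seed: int = 0,
    rate_bp: int = 10_000,
) -> list[Segment]:
    """Single-class control set maximizing taxonomic breadth.

    Selects up to n_genomes of the requested class, one per cluster while
    possible (round-robin across clusters beyond that), then samples
    fixed-length segments from each.
    """
    klass = SeqClass(klass)
    pool = [g for g in genomes if g.seq_class == klass]
    if not pool:
        raise ValidationError(f"no genomes of class {klass.value} available")
    if n_genomes == 0:
        return []
    if n_genomes > len(pool):
        warnings.warn(
            f"requested {n_genomes} genomes, only {len(pool)} available; using all",
            stacklevel=2,
        )
        n_genomes = len(pool)
    rng = np.random.default_rng(seed)
    by_cluster: dict[str, list[GenomeRecord]] = {}
    for g in pool:
        by_cluster.setdefault(g.cluster_id, []).append(g)
    cluster_order = sorted(by_cluster)
    rng.shuffle(cluster_order)
    for c in cluster_order:
        rng.shuffle(by_cluster[c])
    selected: list[GenomeRecord] = []
    rank = 0
    while len(selected) < n_genomes:
        added = False
        for c in cluster_order:
            if rank < len(by_cluster[c]):
                selected.append(by_cluster[c][rank])
                added = True
                if len(selected) == n_genomes:
                    break
        if not added:
            break
        rank += 1
    out: list[Segment] = []
    for g in selected:
        segs = sample_segments(g, seg_len, rate_bp=rate_bp, seed=int(rng.integers(2**31)))
        out.extend(replace(s, label=klass) for s in segs)
    return out


def read_cds_table(path: str | Path) -> pd.DataFrame:
    """Read a CDS annotation TSV: genome_id, start, end, strand, category."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"genome_id", "start", "end", "strand", "category"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def segment_by_cds(
    genome_id: str,
    cds_rows: Sequence[tuple[int, int, str, str]],
    genome_length: int | None = None,
    cluster_id: str = "",
) -> list[Segment]:
    """One variable-length phage-labeled segment per coding sequence.

    Rows are (start, end, strand, phrog_category) in 0-based half-open
    coordinates.  Rows outside the genome bounds or with invalid intervals
    are rejected with a warning.
    """
    out: list[Segment] = []
    n_rejected = 0
    for start, end, strand, category in cds_rows:
        if start < 0 or start >= end or (
            genome_length is not None and end > genome_length
        ):
            n_rejected += 1
            continue
        out.append(
            Segment(
                genome_id=genome_id, start=int(start), end=int(end),
                label=SeqClass.PHAGE, cluster_id=cluster_id,
                category=str(category),
            )
        )
    if n_rejected:
        warnings.warn(
            f"genome {genome_id}: rejected {n_rejected} out-of-bounds CDS row(s)",
            stacklevel=2,
        )
    return out


MANIFEST_COLUMNS = ["genome_id", "start", "end", "label", "cluster_id", "split", "seq"]


def write_manifest(segments: Sequence[Segment], path: str | Path) -> None:
    """Write a dataset manifest TSV (deterministic row order)."""
    has_category = any(s.category is not None for s in segments)
    cols = MANIFEST_COLUMNS + (["category"] if has_category else [])
    rows = []
    for s in sorted(segments, key=lambda s: (s.genome_id, s.start, s.end)):
        row = [s.genome_id, s.start, s.end, s.label.value, s.cluster_id, s.split,
               s.sequence or ""]
        if has_category:
            row.append(s.category or "")
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> list[Segment]:
    df = pd.read_csv(path, sep="\t", dtype={"seq": str}, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing manifest columns {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        out.append(
            Segment(
                genome_id=str(d["genome_id"]), start=int(d["start"]),
                end=int(d["end"]), label=SeqClass(d["label"]),
                cluster_id=str(d["cluster_id"]), split=str(d["split"]),
                sequence=d["seq"] or None,
                category=str(d["category"]) if "category" in d and d["category"] else None,
            )
        )
    return out


def read_genome_metadata(path: str | Path) -> pd.DataFrame:
    """Read a genome metadata TSV: genome_id, class, cluster_id."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"genome_id", "class", "cluster_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def apply_metadata(
    genomes: Sequence[GenomeRecord], metadata: pd.DataFrame
) -> list[GenomeRecord]:
    """Attach class and cluster metadata to genome records."""
    meta = {
        str(gid): (SeqClass(str(klass)), str(cluster))
        for gid, klass, cluster in metadata[
            ["genome_id", "class", "cluster_id"]
        ].itertuples(index=False, name=None)
    }
    out = []
    for g in genomes:
        if g.genome_id in meta:
            klass, cluster = meta[g.genome_id]
            out.append(replace(g, seq_class=klass, cluster_id=cluster))
        else:
            out.append(g)
    return out
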