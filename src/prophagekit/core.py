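"""Shared data model and standard-format I/O.

All genomic intervals use 0-based half-open coordinates internally.  Tables
that arrive in 1-based inclusive coordinates (the common convention of
curated prophage coordinate tables) are converted at ingestion via a
dialect flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

VALID_ALPHABET = frozenset("ACGTN")


class SeqClass(str, Enum):
    """Class of a genome: phage (positive), bacteria (negative), or unknown."""

    PHAGE = "phage"
    BACTERIA = "bacteria"
    UNKNOWN = "unknown"


@dataclass
class GenomeRecord:
    """A nucleotide sequence with class, cluster and taxon metadata.

    ``cluster_id`` is an ANI cluster for phages or a genus for bacteria; it is
    consumed verbatim from metadata tables and drives leakage-free splitting.
    """

    genome_id: str
    sequence: str
    seq_class: SeqClass = SeqClass.UNKNOWN
    cluster_id: str = ""

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValidationError("genome_id must be non-empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise FormatError(
                f"genome {self.genome_id!r}: invalid characters {sorted(bad)!r} "
                "(alphabet is A, C, G, T, N)"
            )
        if isinstance(self.seq_class, str):
            self.seq_class = SeqClass(self.seq_class)

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    def gc_fraction(self) -> float:
        """Fraction of G+C bases; N counts as non-GC."""
        if not self.sequence:
            return 0.0
        gc = self.sequence.count("G") + self.sequence.count("C")
        return gc / len(self.sequence)


@dataclass
class Region:
    """A half-open genomic interval [start, end) with optional score/source."""

    genome_id: str
    start: int
    end: int
    score: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"region {self.genome_id}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        """True iff the two regions share >= 1 base (half-open semantics)."""
        return (
            self.genome_id == other.genome_id
            and max(self.start, other.start) < min(self.end, other.end)
        )


@dataclass
class ScoreTrack:
    """Ordered per-window phage probabilities for one genome.

    Windows have fixed length and fixed step; the canonical scan uses 50%
    overlap (step = window_length / 2).
    """

    genome_id: str
    window_length: int
    step: int
    window_starts: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.window_starts = np.asarray(self.window_starts, dtype=np.int64)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.window_starts.shape != self.probabilities.shape:
            raise ValidationError("window_starts and probabilities differ in length")
        if self.window_starts.size == 0:
            raise ValidationError(f"track {self.genome_id}: no windows")
        if self.step <= 0 or self.step > self.window_length:
            raise ValidationError(
                f"track {self.genome_id}: require 0 < step <= window_length"
            )
        diffs = np.diff(self.window_starts)
        if diffs.size and not np.all(diffs == self.step):
            raise ValidationError(
                f"track {self.genome_id}: window spacing is not a constant "
                f"step of {self.step}"
            )
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValidationError(
                f"track {self.genome_id}: probabilities outside [0, 1]"
            )

    @property
    def n_windows(self) -> int:
        return int(self.window_starts.size)

    @property
    def span_end(self) -> int:
        """End coordinate of the scanned span."""
        return int(self.window_starts[-1]) + self.window_length


@dataclass
class SegmentScores:
    """One collapsed score per non-overlapping step-sized segment."""

    genome_id: str
    step: int
    segment_starts: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.segment_starts = np.asarray(self.segment_starts, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.segment_starts.shape != self.values.shape:
            raise ValidationError("segment_starts and values differ in length")
        if self.step <= 0:
            raise ValidationError("step must be positive")


@dataclass
class ConfusionCounts:
    """TP/FP/FN/TN aggregate from which all ratio metrics derive."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _strip_version(genome_id: str) -> str:
    head, sep, tail = genome_id.rpartition(".")
    if sep and tail.isdigit():
        return head
    return genome_id


def read_fasta(
    path: str | Path,
    seq_class: SeqClass | str = SeqClass.UNKNOWN,
    strip_version: bool = False,
) -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords (sequences uppercased).

    Metadata fields default to unknown; class/cluster assignment normally
    comes from a separate metadata table.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        gid = entry.id
        if not gid:
            raise FormatError(f"{path}: FASTA entry with empty header")
        if strip_version:
            gid = _strip_version(gid)
        seq = str(entry.seq)
        if not seq:
            raise FormatError(f"{path}: record {gid!r} has an empty sequence")
        if gid in seen:
            raise FormatError(f"{path}: duplicate genome id {gid!r}")
        seen.add(gid)
        records.append(GenomeRecord(genome_id=gid, sequence=seq, seq_class=seq_class))
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.genome_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_regions(
    path: str | Path,
    dialect: str = "bed",
    strip_version: bool = False,
) -> list[Region]:
    """Read genomic intervals from a BED-like table.

    dialect "bed": 0-based half-open (used as-is); dialect
    "one_based_inclusive_tsv": row (id, a, b) maps to [a-1, b).  Optional
    columns 4-5 are score and source ('.' = absent).
    """
    if dialect not in ("bed", "one_based_inclusive_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected >= 3 columns (id, start, end)")
    regions: list[Region] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        gid = str(row[0])
        if strip_version:
            gid = _strip_version(gid)
        try:
            a, b = int(row[1]), int(row[2])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path} row {row_no}: non-integer coordinates") from exc
        if dialect == "one_based_inclusive_tsv":
            start, end = a - 1, b
        else:
            start, end = a, b
        if start < 0 or start >= end:
            raise ValidationError(
                f"{path} row {row_no}: invalid interval [{start}, {end}) "
                "after normalization"
            )
        score = None
        source = None
        if len(row) > 3 and str(row[3]) not in (".", "nan"):
            score = float(row[3])
        if len(row) > 4 and str(row[4]) not in (".", "nan"):
            source = str(row[4])
        regions.append(Region(gid, start, end, score=score, source=source))
    return regions


def write_bed(regions: Sequence[Region], path: str | Path) -> None:
    """Write regions as BED3 plus score/source columns when any are set."""
    extended = any(r.score is not None or r.source is not None for r in regions)
    with open(path, "w") as fh:
        for r in regions:
            cols = [r.genome_id, str(r.start), str(r.end)]
            if extended:
                cols.append("." if r.score is None else repr(float(r.score)))
                cols.append("." if r.source is None else r.source)
            fh.write("\t".join(cols) + "\n")


def read_score_track(path: str | Path) -> list[ScoreTrack]:
    """Read per-window probability tracks from a TSV.

    Columns: genome_id, window_start, window_length, probability.  One
    window_length per genome; constant spacing between successive windows.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"genome_id", "window_start", "window_length", "probability"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    tracks: list[ScoreTrack] = []
    for gid, grp in df.groupby("genome_id", sort=True):
        grp = grp.sort_values("window_start")
        lengths = grp["window_length"].unique()
        if len(lengths) != 1:
            raise ValidationError(
                f"{path}: genome {gid}: multiple window lengths {sorted(lengths)}"
            )
        window_length = int(lengths[0])
        starts = grp["window_start"].to_numpy(dtype=np.int64)
        probs = grp["probability"].to_numpy(dtype=float)
        if np.any((probs < 0) | (probs > 1)):
            raise ValidationError(f"{path}: genome {gid}: probability outside [0, 1]")
        if starts.size > 1:
            diffs = np.diff(starts)
            step = int(diffs[0])
            if not np.all(diffs == step):
                raise ValidationError(
                    f"{path}: genome {gid}: irregular window spacing "
                    f"{sorted(set(diffs.tolist()))}"
                )
        else:
            step = window_length
        tracks.append(
            ScoreTrack(
                genome_id=str(gid),
                window_length=window_length,
                step=step,
                window_starts=starts,
                probabilities=probs,
            )
        )
    return tracks


def write_score_track(tracks: Iterable[ScoreTrack], path: str | Path) -> None:
    rows = []
    for t in tracks:
        for s, p in zip(t.window_starts, t.probabilities):
            rows.append((t.genome_id, int(s), t.window_length, float(p)))
    pd.DataFrame(
        rows, columns=["genome_id", "window_start", "window_length", "probability"]
    ).to_csv(path, sep="\t", index=False)


def read_genome_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV `genome_id<TAB>length` into a dict."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected 2 columns (genome_id, length)")
    out: dict[str, int] = {}
    for row in df.itertuples(index=False):
        out[str(row[0])] = int(row[1])
    return out


def merge_intervals(regions: Sequence[Region]) -> list[Region]:
    """Union of overlapping (>= 1 shared base) intervals per genome.

    Touching half-open intervals ([a,b) and [b,c)) are NOT merged.
    """
    by_genome: dict[str, list[Region]] = {}
    for r in regions:
        by_genome.setdefault(r.genome_id, []).append(r)
    merged: list[Region] = []
    for gid in sorted(by_genome):
        regs = sorted(by_genome[gid], key=lambda r: (r.start, r.end))
        cur_start, cur_end = regs[0].start, regs[0].end
        for r in regs[1:]:
            if r.start < cur_end:
                cur_end = max(cur_end, r.end)
            else:
                merged.append(Region(gid, cur_start, cur_end))
                cur_start, cur_end = r.start, r.end
        merged.append(Region(gid, cur_start, cur_end))
    return merged
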