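"""Synthetic fixtures: every input the toolkit consumes, generated from seeds.

Genomes are i.i.d. nucleotide sequences with a controlled GC fraction;
prophage implants are composition-shifted blocks with recorded truth
intervals.  Score tracks are generated directly from the truth (elevated
in-implant probability over a genome-specific baseline offset plus window
noise), decoupling tests of the signal-extraction algorithm from any
particular sequence classifier.  Embedding clouds are class-conditional
isotropic Gaussians whose mean separation models representational strength.

Also provides synthetic stand-ins for published bookkeeping tables (a
genome-wide ground-truth coordinate table and a candidate gene-content
review table) whose aggregate shapes match the published counts; these are
synthetic fixtures, not the original curated data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import GenomeRecord, Region, ScoreTrack, SeqClass
from .errors import ValidationError
from .probing import EmbeddingSet
from .screening import Classification, GeneContent

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimSpec:
    """Default study conditions for the end-to-end pipeline simulation.

    Five 300 kb genomes, each carrying two 40 kb prophage-like implants; the
    scan uses 2 kb windows at 50% overlap; in-implant windows score around
    0.9 and background windows around 0.1 before the genome-specific
    baseline offset (sd 0.1) and per-window noise (sd 0.1).  Implants are
    GC-shifted (0.40 vs the host's 0.50) so sequence-level composition
    signal exists as well.
    """

    n_genomes: int = 5
    genome_length: int = 300_000
    background_gc: float = 0.50
    implant_gc: float = 0.40
    implants_per_genome: int = 2
    implant_length: int = 40_000
    window_length: int = 2000
    step: int = 1000
    signal_mean: float = 0.9
    noise_sd: float = 0.1
    baseline_shift_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.background_gc < 1 and 0 < self.implant_gc < 1):
            raise ValidationError("GC fractions must lie in (0, 1)")
        if self.implant_length * self.implants_per_genome >= self.genome_length:
            raise ValidationError("implants do not fit in the genome")
        if self.noise_sd < 0 or self.baseline_shift_sd < 0:
            raise ValidationError("noise levels must be non-negative")


def simulate_genome(
    length: int, gc: float, seed: int, genome_id: str = "sim",
    seq_class: SeqClass = SeqClass.BACTERIA, cluster_id: str = "",
) -> GenomeRecord:
    """An i.i.d. random genome with P(G)+P(C) = gc, split evenly."""
    if length < 1:
        raise ValidationError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(BASES, size=length, p=p))
    return GenomeRecord(genome_id, seq, seq_class=seq_class, cluster_id=cluster_id)


def implant_prophages(
    genome: GenomeRecord, spec: SimSpec, seed: int | None = None
) -> tuple[GenomeRecord, list[Region]]:
    """Replace random non-overlapping blocks with implant-GC sequence."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    L, k, ilen = genome.length_nt, spec.implants_per_genome, spec.implant_length
    if k == 0:
        return genome, []
    placed: list[tuple[int, int]] = []
    attempts = 0
    while len(placed) < k:
        attempts += 1
        if attempts > 1000 * k:
            raise ValidationError("could not place non-overlapping implants")
        s = int(rng.integers(0, L - ilen + 1))
        if all(s + ilen <= a or s >= b for a, b in placed):
            placed.append((s, s + ilen))
    placed.sort()
    seq = list(genome.sequence)
    p = np.array([
        (1 - spec.implant_gc) / 2, spec.implant_gc / 2,
        spec.implant_gc / 2, (1 - spec.implant_gc) / 2,
    ])
    for a, b in placed:
        seq[a:b] = rng.choice(BASES, size=b - a, p=p)
    truth = [Region(genome.genome_id, a, b) for a, b in placed]
    return replace(genome, sequence="".join(seq)), truth


def simulate_score_track(
    truth: Sequence[Region],
    genome_length: int,
    spec: SimSpec,
    seed: int,
    genome_id: str = "sim",
) -> ScoreTrack:
    """Per-window probabilities from truth: signal in implants, noise outside.

    A window scores ``signal_mean`` when >= 50% of its bases lie in a truth
    region and ``1 - signal_mean`` otherwise; one genome-level baseline
    offset ~ N(0, baseline_shift_sd) and per-window N(0, noise_sd) noise are
    added before clipping to [0, 1].
    """
    rng = np.random.default_rng(seed)
    starts = np.arange(0, genome_length - spec.window_length + 1, spec.step)
    base = np.full(starts.size, 1.0 - spec.signal_mean)
    for r in truth:
        overlap = np.minimum(starts + spec.window_length, r.end) - np.maximum(
            starts, r.start
        )
        base[overlap >= spec.window_length / 2] = spec.signal_mean
    offset = rng.normal(0.0, spec.baseline_shift_sd) if spec.baseline_shift_sd else 0.0
    noise = rng.normal(0.0, spec.noise_sd, size=starts.size) if spec.noise_sd else 0.0
    probs = np.clip(base + offset + noise, 0.0, 1.0)
    return ScoreTrack(
        genome_id=genome_id, window_length=spec.window_length, step=spec.step,
        window_starts=starts, probabilities=probs,
    )


def simulate_benchmark(
    spec: SimSpec = SimSpec(), seed: int | None = None
) -> tuple[list[GenomeRecord], list[Region], list[ScoreTrack]]:
    """Genomes + implanted truth + score tracks for the full pipeline."""
    root_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(root_seed)
    genomes, truth, tracks = [], [], []
    for i in range(spec.n_genomes):
        gid = f"sim_{i:03d}"
        g = simulate_genome(
            spec.genome_length, spec.background_gc, int(rng.integers(2**31)),
            genome_id=gid, seq_class=SeqClass.BACTERIA, cluster_id=f"genus_{i:03d}",
        )
        g, t = implant_prophages(g, spec, seed=int(rng.integers(2**31)))
        track = simulate_score_track(
            t, g.length_nt, spec, int(rng.integers(2**31)), genome_id=gid
        )
        genomes.append(g)
        truth.extend(t)
        tracks.append(track)
    return genomes, truth, tracks


def simulate_embeddings(
    n_per_class: int,
    dim: int,
    separation: float,
    seed: int = 0,
    weak_factor: float = 5.0,
) -> tuple[dict[str, EmbeddingSet], dict[str, EmbeddingSet]]:
    """Strong and weak class-conditional Gaussian embedding clouds.

    Both classes are unit-variance isotropic Gaussians; class means are
    ``separation`` apart for the strong ("pretrained") clouds and
    ``separation / weak_factor`` apart for the weak ("random_init") clouds.
    Each is split 8:1:1 into train/dev/test.
    """
    if dim < 1:
        raise ValidationError("dim must be >= 1")
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=dim)
    direction /= np.linalg.norm(direction)

    def _make(sep: float, provenance: str, child_seed: int) -> dict[str, EmbeddingSet]:
        r = np.random.default_rng(child_seed)
        mu = direction * sep / 2
        X0 = r.normal(size=(n_per_class, dim)) - mu
        X1 = r.normal(size=(n_per_class, dim)) + mu
        X = np.vstack([X0, X1])
        y = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
        perm = r.permutation(X.shape[0])
        X, y = X[perm], y[perm]
        n = X.shape[0]
        n_train = int(round(0.8 * n))
        n_dev = int(round(0.1 * n))
        bounds = {
            "train": (0, n_train),
            "dev": (n_train, n_train + n_dev),
            "test": (n_train + n_dev, n),
        }
        return {
            split: EmbeddingSet(X[a:b], y[a:b], provenance=provenance, split=split)
            for split, (a, b) in bounds.items()
        }

    strong = _make(separation, "pretrained", int(rng.integers(2**31)))
    weak = _make(separation / weak_factor, "random_init", int(rng.integers(2**31)))
    return strong, weak


# ---------------------------------------------------------------------------
# Synthetic stand-ins for published bookkeeping tables
# ---------------------------------------------------------------------------

#: Published shape of the genome-wide evaluation set: 80 bacterial genomes
#: carrying 386 verified prophage locations.
TRUTH_TABLE_GENOMES = 80
TRUTH_TABLE_PROPHAGES = 386

#: Published candidate-review label distribution over 305 consensus regions.
CANDIDATE_REVIEW_COUNTS: dict[Classification, int] = {
    Classification.LIKELY_PHAGE: 22,
    Classification.POSSIBLE_PHAGE: 92,
    Classification.WEAK_SIGNAL: 113,
    Classification.GENOMIC_ISLAND_ICE: 31,
    Classification.GENOMIC_ISLAND: 16,
    Classification.UNLIKELY_PHAGE: 31,
}


def synthetic_truth_table(
    n_genomes: int = TRUTH_TABLE_GENOMES,
    n_prophages: int = TRUTH_TABLE_PROPHAGES,
    seed: int = 0,
) -> tuple[dict[str, int], list[Region]]:
    """Synthetic genome-wide ground-truth annotations.

    A stand-in with the published aggregate shape (genome and prophage
    counts): every genome carries at least one prophage, the remainder are
    spread at random; genome lengths and prophage lengths are drawn from
    realistic ranges (2-6 Mb hosts, 15-60 kb prophages).
    """
    if n_prophages < n_genomes:
        raise ValidationError("need at least one prophage per genome")
    rng = np.random.default_rng(seed)
    lengths = {
        f"SYN_{i:04d}": int(rng.integers(2_000_000, 6_000_000))
        for i in range(n_genomes)
    }
    per_genome = np.ones(n_genomes, dtype=int)
    extra = rng.choice(n_genomes, size=n_prophages - n_genomes, replace=True)
    np.add.at(per_genome, extra, 1)
    regions: list[Region] = []
    for i, (gid, L) in enumerate(lengths.items()):
        k = int(per_genome[i])
        placed: list[tuple[int, int]] = []
        while len(placed) < k:
            ilen = int(rng.integers(15_000, 60_000))
            s = int(rng.integers(0, L - ilen))
            if all(s + ilen <= a or s >= b for a, b in placed):
                placed.append((s, s + ilen))
        regions.extend(Region(gid, a, b) for a, b in sorted(placed))
    return lengths, regions


def write_truth_table(
    regions: Sequence[Region], path: str | Path, dialect: str = "one_based_inclusive_tsv"
) -> None:
    """Serialize truth annotations as an accession/start/end TSV."""
    with open(path, "w") as fh:
        fh.write("# accession\tstart\tend\n")
        for r in regions:
            if dialect == "one_based_inclusive_tsv":
                fh.write(f"{r.genome_id}\t{r.start + 1}\t{r.end}\n")
            else:
                fh.write(f"{r.genome_id}\t{r.start}\t{r.end}\n")


def synthetic_candidate_review(
    counts: Mapping[Classification, int] | None = None,
    seed: int = 0,
) -> dict[str, GeneContent]:
    """Synthetic gene-content records realizing a review label distribution.

    For each label, gene contents are sampled inside the corresponding
    rule's region of the input space, so classifying the records recovers
    the distribution.  Record order is shuffled; ids are candidate_0..N-1.
    """
    counts = dict(CANDIDATE_REVIEW_COUNTS if counts is None else counts)
    rng = np.random.default_rng(seed)
    records: list[GeneContent] = []
    for label, n in counts.items():
        for _ in range(n):
            n_genes = int(rng.integers(20, 81))
            if label is Classification.LIKELY_PHAGE:
                n_struct = int(np.ceil(0.10 * n_genes)) + int(rng.integers(0, 5))
                g = GeneContent(n_genes, min(n_struct, n_genes),
                                has_head_or_tail=True,
                                has_lysis=bool(rng.integers(0, 2)))
            elif label is Classification.POSSIBLE_PHAGE:
                # need >= 3 structural genes (1-2 would be weak_signal) in
                # the [0.05, 0.10) band, so use larger gene counts
                n_genes = int(rng.integers(40, 81))
                lo = max(3, int(np.ceil(0.05 * n_genes)))
                hi = int(np.ceil(0.10 * n_genes)) - 1
                g = GeneContent(n_genes, int(rng.integers(lo, hi + 1)),
                                has_head_or_tail=bool(rng.integers(0, 2)))
            elif label is Classification.WEAK_SIGNAL:
                n_genes = int(rng.integers(41, 101))  # keeps frac below 0.05
                g = GeneContent(n_genes, int(rng.integers(1, 3)))
            elif label is Classification.GENOMIC_ISLAND_ICE:
                g = GeneContent(n_genes, 0, has_integrase_or_excision=True,
                                has_conjugation=True)
            elif label is Classification.GENOMIC_ISLAND:
                g = GeneContent(n_genes, 0, has_integrase_or_excision=True)
            elif label is Classification.UNLIKELY_PHAGE:
                g = GeneContent(n_genes, 0)
            else:
                raise ValidationError(f"cannot synthesize label {label}")
            records.append(g)
    order = rng.permutation(len(records))
    return {f"candidate_{i}": records[j] for i, j in enumerate(order)}
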