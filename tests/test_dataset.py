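"""Benchmark dataset construction: filtering, sampling, splitting, controls."""

from collections import Counter

import pytest

from prophagekit import (
    AlignmentHit,
    GenomeRecord,
    SeqClass,
    SplitRatios,
    ValidationError,
    balance_classes,
    build_class_control,
    sample_segments,
    segment_by_cds,
    shuffle_gc_control,
    split_by_cluster,
)
from prophagekit.dataset import Segment, filter_contaminated, read_manifest, write_manifest
from prophagekit.simulate import simulate_genome


def bacterium(gid, length=30_000, cluster=None, seed=0):
    g = simulate_genome(length, 0.5, seed=seed, genome_id=gid,
                        seq_class=SeqClass.BACTERIA)
    from dataclasses import replace

    return replace(g, cluster_id=cluster or f"genus_{gid}")


class TestContaminationFilter:
    def test_hit_above_both_thresholds_excludes(self):
        g = bacterium("b1")
        kept, excluded = filter_contaminated([g], [AlignmentHit("p1", "b1", 95, 250)])
        assert excluded == ["b1"] and kept == []

    def test_below_length_threshold_keeps(self):
        g = bacterium("b1")
        kept, excluded = filter_contaminated([g], [AlignmentHit("p1", "b1", 95, 150)])
        assert excluded == [] and kept == [g]

    def test_below_identity_threshold_keeps(self):
        g = bacterium("b1")
        kept, excluded = filter_contaminated([g], [AlignmentHit("p1", "b1", 85, 300)])
        assert excluded == []

    def test_no_hits_keeps(self):
        g = bacterium("b1")
        kept, excluded = filter_contaminated([g], [])
        assert kept == [g]

    def test_both_orientations_accepted(self):
        g = bacterium("b1")
        _, excluded = filter_contaminated([g], [AlignmentHit("b1", "p1", 95, 250)])
        assert excluded == ["b1"]

    def test_unknown_id_warns_and_is_ignored(self):
        g = bacterium("b1")
        with pytest.warns(UserWarning, match="ignored"):
            kept, excluded = filter_contaminated(
                [g], [AlignmentHit("p1", "bX", 99, 999)]
            )
        assert kept == [g]

    def test_rerunning_predicate_flags_no_kept_genome(self, rng):
        genomes = [bacterium(f"b{i}", seed=i) for i in range(20)]
        hits = [
            AlignmentHit(
                f"p{i}", f"b{int(rng.integers(0, 20))}",
                float(rng.uniform(80, 100)), int(rng.integers(100, 400)),
            )
            for i in range(50)
        ]
        kept, excluded = filter_contaminated(genomes, hits)
        kept_ids = {g.genome_id for g in kept}
        for h in hits:
            if h.alignment_length >= 200 and h.percent_identity >= 90:
                assert h.subject_id not in kept_ids


class TestSampleSegments:
    @pytest.mark.parametrize("length,expected", [(5000, 1), (25_000, 2), (100_000, 10)])
    def test_count_follows_rate_with_minimum_one(self, length, expected):
        g = bacterium("b", length=length)
        assert len(sample_segments(g, 2000, seed=1)) == expected

    def test_segments_nonoverlapping_and_in_bounds(self):
        g = bacterium("b", length=50_000)
        segs = sample_segments(g, 4000, seed=3)
        segs.sort(key=lambda s: s.start)
        for s in segs:
            assert 0 <= s.start and s.end <= 50_000 and s.length == 4000
        for a, b in zip(segs, segs[1:]):
            assert a.end <= b.start

    def test_reproducible_from_seed(self):
        g = bacterium("b", length=80_000)
        assert sample_segments(g, 2000, seed=7) == sample_segments(g, 2000, seed=7)

    def test_short_genome_skipped_with_warning(self):
        g = bacterium("b", length=1000)
        with pytest.warns(UserWarning, match="skipped"):
            assert sample_segments(g, 2000) == []


class TestBalanceClasses:
    def _phage_segments(self, n):
        return [
            Segment(f"p{i}", 0, 2000, SeqClass.PHAGE, f"c{i}") for i in range(n)
        ]

    def test_round_robin_parity(self):
        bacteria = [bacterium(f"b{i}", length=30_000, seed=i) for i in range(50)]
        segs = balance_classes(self._phage_segments(100), bacteria, 2000, seed=1)
        assert len(segs) == 100
        counts = Counter(s.genome_id for s in segs)
        assert set(counts.values()) == {2}

    def test_few_segments_use_distinct_genomes(self):
        bacteria = [bacterium(f"b{i}", length=30_000, seed=i) for i in range(5)]
        segs = balance_classes(self._phage_segments(3), bacteria, 2000, seed=1)
        assert len(segs) == 3
        assert len({s.genome_id for s in segs}) == 3

    def test_zero_phage_segments(self):
        assert balance_classes([], [bacterium("b1")], 2000) == []

    def test_parity_unreachable_raises(self):
        bacteria = [bacterium("b1", length=4000)]
        with pytest.raises(ValidationError, match="balance"):
            balance_classes(self._phage_segments(10), bacteria, 2000, seed=1)

    def test_nonoverlap_within_genome(self):
        bacteria = [bacterium("b1", length=40_000)]
        segs = balance_classes(self._phage_segments(10), bacteria, 2000, seed=2)
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            assert a.end <= b.start


class TestSplitByCluster:
    def _segments(self, cluster_sizes, klass=SeqClass.PHAGE):
        segs = []
        for ci, size in enumerate(cluster_sizes):
            for j in range(size):
                segs.append(
                    Segment(f"g{ci}_{j}", 0, 2000, klass, f"c{ci}")
                )
        return segs

    def test_ten_equal_clusters_split_8_1_1(self):
        segs = split_by_cluster(self._segments([4] * 10), seed=0)
        cluster_split = {s.cluster_id: s.split for s in segs}
        counts = Counter(cluster_split.values())
        assert counts == {"train": 8, "dev": 1, "test": 1}

    def test_no_cluster_straddles_splits(self, rng):
        sizes = [int(rng.integers(1, 30)) for _ in range(25)]
        segs = split_by_cluster(self._segments(sizes), seed=4)
        per_cluster = {}
        for s in segs:
            per_cluster.setdefault(s.cluster_id, set()).add(s.split)
        assert all(len(v) == 1 for v in per_cluster.values())

    def test_uneven_clusters_match_exhaustive_optimum(self):
        # brute force over all 3^4 assignments of clusters sized 50,30,10,10
        sizes = [50, 30, 10, 10]
        segs = split_by_cluster(self._segments(sizes), seed=0)
        assign = {s.cluster_id: s.split for s in segs}
        got = {
            name: sum(sizes[i] for i in range(4) if assign[f"c{i}"] == name)
            for name in ("train", "dev", "test")
        }
        import itertools

        def deviation(counts):
            total = sum(sizes)
            ratios = {"train": 0.8, "dev": 0.1, "test": 0.1}
            return sum(abs(counts[n] - ratios[n] * total) for n in counts)

        best = min(
            (
                {
                    name: sum(
                        sizes[i] for i in range(4) if combo[i] == name
                    )
                    for name in ("train", "dev", "test")
                }
                for combo in itertools.product(("train", "dev", "test"), repeat=4)
            ),
            key=deviation,
        )
        assert deviation(got) == deviation(best)
        assert got == {"train": 80, "dev": 10, "test": 10}

    def test_fewer_than_three_clusters_raises(self):
        with pytest.raises(ValidationError, match="cluster"):
            split_by_cluster(self._segments([5, 5]), seed=0)

    def test_classes_split_independently(self):
        segs = self._segments([3] * 6, SeqClass.PHAGE) + self._segments(
            [3] * 6, SeqClass.BACTERIA
        )
        out = split_by_cluster(segs, seed=1)
        for klass in (SeqClass.PHAGE, SeqClass.BACTERIA):
            splits = {s.split for s in out if s.label == klass}
            assert splits == {"train", "dev", "test"}

    def test_missing_cluster_id_raises(self):
        with pytest.raises(ValidationError):
            split_by_cluster([Segment("g", 0, 10, SeqClass.PHAGE, "")])

    def test_ratios_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            SplitRatios(0.5, 0.2, 0.2)


class TestGCShuffle:
    def test_single_letter_fixed_point(self):
        assert shuffle_gc_control("AAAA", seed=1) == "AAAA"

    def test_multiset_preserved(self):
        out = shuffle_gc_control("ACGT", seed=2)
        assert sorted(out) == list("ACGT")

    def test_deterministic_given_seed(self):
        seq = simulate_genome(5000, 0.5, seed=9).sequence
        assert shuffle_gc_control(seq, seed=3) == shuffle_gc_control(seq, seed=3)

    def test_dinucleotide_counts_differ_for_long_sequences(self):
        def dinucs(s):
            return Counter(s[i : i + 2] for i in range(len(s) - 1))

        seq = simulate_genome(10_000, 0.5, seed=11).sequence
        differing = sum(
            dinucs(shuffle_gc_control(seq, seed=s)) != dinucs(seq) for s in range(20)
        )
        assert differing == 20

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            shuffle_gc_control("")


class TestClassControl:
    def test_selection_maximizes_cluster_diversity(self):
        genomes = [
            bacterium(f"b{i}", length=30_000, cluster=f"genus_{i % 150}", seed=i)
            for i in range(200)
        ]
        segs = build_class_control(genomes, SeqClass.BACTERIA, 100, 2000, seed=1)
        used = {s.genome_id for s in segs}
        clusters = {
            g.cluster_id for g in genomes if g.genome_id in used
        }
        assert len(clusters) == 100  # one genome per genus while possible

    def test_all_labels_forced_to_class(self):
        genomes = [bacterium(f"b{i}", seed=i) for i in range(5)]
        segs = build_class_control(genomes, SeqClass.BACTERIA, 3, 2000, seed=0)
        assert all(s.label == SeqClass.BACTERIA for s in segs)

    def test_zero_genomes_empty(self):
        genomes = [bacterium("b1")]
        assert build_class_control(genomes, SeqClass.BACTERIA, 0, 2000) == []

    def test_requesting_too_many_warns(self):
        genomes = [bacterium(f"b{i}", seed=i) for i in range(2)]
        with pytest.warns(UserWarning, match="available"):
            build_class_control(genomes, SeqClass.BACTERIA, 10, 2000, seed=0)


class TestSegmentByCDS:
    def test_one_segment_per_cds_with_category(self):
        rows = [(0, 300, "+", "tail"), (100, 400, "-", "head and packaging"),
                (500, 800, "+", "unknown function")]
        segs = segment_by_cds("g1", rows, genome_length=1000)
        assert len(segs) == 3
        assert segs[1].length == 300
        assert segs[2].category == "unknown function"
        assert all(s.label == SeqClass.PHAGE for s in segs)

    def test_out_of_bounds_rejected_with_warning(self):
        with pytest.warns(UserWarning, match="rejected"):
            segs = segment_by_cds("g1", [(0, 300, "+", "tail"), (900, 1200, "+", "tail")],
                                  genome_length=1000)
        assert len(segs) == 1


def test_manifest_round_trip(tmp_path):
    segs = [
        Segment("g1", 0, 2000, SeqClass.PHAGE, "c1", split="train", sequence="ACGT"),
        Segment("g2", 10, 400, SeqClass.BACTERIA, "c2", split="test",
                category="tail", sequence="GGCC"),
    ]
    path = tmp_path / "manifest.tsv"
    write_manifest(segs, path)
    back = read_manifest(path)
    assert back == sorted(segs, key=lambda s: (s.genome_id, s.start, s.end))


def test_identical_seeds_reproduce_identical_manifests(tmp_path):
    genomes = [bacterium(f"b{i}", length=60_000, seed=i) for i in range(6)]
    phage = [
        Segment(f"p{i}", 0, 2000, SeqClass.PHAGE, f"c{i % 4}") for i in range(12)
    ]
    for name in ("a.tsv", "b.tsv"):
        segs = balance_classes(phage, genomes, 2000, seed=5)
        out = split_by_cluster(phage + segs, seed=5)
        write_manifest(out, tmp_path / name)
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
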