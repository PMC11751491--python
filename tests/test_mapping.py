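"""Pattern alignment, hit adjustment, and location voting."""

import numpy as np
import pytest

from dietmap import (
    AdjustedHit,
    PatternAlignConfig,
    adjust_and_sort_hits,
    build_index,
    compressed_seed,
    parse_pattern,
    pattern_align,
    rescue_location,
    segment_ultralong,
    vote_long,
    vote_short,
)
from dietmap.mapping import _cluster

from _helpers import cluster_oracle, random_dna, revcomp


def hits_from_deltas(deltas, ref_id=0, read_pos=0, strand=0):
    return [
        AdjustedHit(ref_id=ref_id, delta=d, ref_pos=d + read_pos, read_pos=read_pos, strand=strand)
        for d in sorted(deltas)
    ]


class TestPatternAlign:
    def test_single_phase_pattern(self, small_genome):
        idx = build_index([small_genome], parse_pattern("11"), 19, 16)
        read = small_genome[1][1000:1150]
        assert pattern_align(read, idx.pattern, idx) == 0

    def test_recovers_origin_phase(self, small_genome, small_index):
        # exact reads: chosen shift must match the origin offset mod p
        name, seq = small_genome
        rng = np.random.default_rng(3)
        correct = 0
        n = 100
        for _ in range(n):
            o = int(rng.integers(0, len(seq) - 500))
            read = seq[o : o + 500]
            a = pattern_align(read, small_index.pattern, small_index)
            correct += a == o % 2
        assert correct >= 0.97 * n

    def test_all_n_read_returns_zero(self, small_index):
        assert pattern_align("N" * 200, small_index.pattern, small_index) == 0

    def test_t_cap_validated(self):
        with pytest.raises(ValueError):
            PatternAlignConfig(t=0)


class TestCompressedSeed:
    def test_exact_read_seeds_present_in_index(self, small_genome, small_index):
        seq = small_genome[1]
        o = 5000
        read = seq[o : o + 400]
        a = pattern_align(read, small_index.pattern, small_index)
        ms = compressed_seed(read, small_index.pattern, a, 19, 16)
        assert len(ms) >= 1
        assert any(small_index.occurrence(int(h)) > 0 for h in ms.hashes)

    def test_too_short_read_empty(self, small_index):
        ms = compressed_seed("ACGTACGT", small_index.pattern, 0, 19, 16)
        assert len(ms) == 0

    def test_identity_pattern_is_plain_sketch(self, rng):
        from dietmap import encode_sequence, extract_minimizers

        read = random_dna(rng, 300)
        ms = compressed_seed(read, parse_pattern("11"), 0, 13, 8)
        plain = extract_minimizers(encode_sequence(read), 13, 8)
        assert ms.hashes.tolist() == plain.hashes.tolist()
        assert ms.positions.tolist() == plain.positions.tolist()


class TestAdjustAndSort:
    def test_one_seed_three_locations(self):
        # hand-built index: one hash at three reference positions
        from dietmap.index import SeedIndex
        from dietmap.sketch import MinimizerSet

        idx = SeedIndex(
            pattern=parse_pattern("11"),
            k=5,
            w=1,
            max_occ=500,
            names=["r"],
            lengths=np.array([1000]),
            hashes=np.array([42, 42, 42], dtype=np.uint64),
            ref_ids=np.zeros(3, dtype=np.int32),
            positions=np.array([100, 300, 700], dtype=np.int64),
            strands=np.zeros(3, dtype=np.uint8),
            spans=np.full(3, 5, dtype=np.int64),
        )
        minis = MinimizerSet(
            hashes=np.array([42], dtype=np.uint64),
            positions=np.array([10], dtype=np.int64),
            strands=np.zeros(1, dtype=np.uint8),
            spans=np.array([5], dtype=np.int64),
            k=5,
            w=1,
        )
        fwd, rev = adjust_and_sort_hits(minis, idx, read_len=50)
        assert [h.delta for h in fwd] == [90, 290, 690]
        assert rev == []

    def test_merge_equals_comparison_sort(self, small_genome, small_index):
        seq = small_genome[1]
        rng = np.random.default_rng(8)
        for _ in range(10):
            o = int(rng.integers(0, len(seq) - 2000))
            read = seq[o : o + 2000]
            a = pattern_align(read, small_index.pattern, small_index)
            ms = compressed_seed(read, small_index.pattern, a, 19, 16)
            fwd, rev = adjust_and_sort_hits(ms, small_index, len(read))
            for hits in (fwd, rev):
                keys = [(h.ref_id, h.delta, h.ref_pos, h.read_pos) for h in hits]
                assert keys == sorted(keys)  # merge == generic sort
                assert len(keys) == len(set(keys))  # duplicates appear once

    def test_no_seeds_empty(self, small_index):
        from dietmap.sketch import MinimizerSet

        empty = MinimizerSet(
            hashes=np.empty(0, dtype=np.uint64),
            positions=np.empty(0, dtype=np.int64),
            strands=np.empty(0, dtype=np.uint8),
            spans=np.empty(0, dtype=np.int64),
            k=19,
            w=16,
        )
        assert adjust_and_sort_hits(empty, small_index, 100) == ([], [])


class TestVoting:
    def test_all_within_distance(self):
        clusters = vote_short(hits_from_deltas([100, 101, 150]), D=60, V=2)
        assert len(clusters) == 1
        assert clusters[0].votes == 3
        assert clusters[0].anchor == 100
        assert clusters[0].last == 150

    def test_two_separate_clusters(self):
        clusters = vote_short(hits_from_deltas([0, 200]), D=100, V=1)
        assert [c.votes for c in clusters] == [1, 1]

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 60))
            deltas = sorted(rng.integers(0, 2000, size=n).tolist())
            D = int(rng.integers(1, 300))
            got = _cluster(hits_from_deltas(deltas), D, 0)
            want = cluster_oracle(deltas, D)
            assert [(c.anchor, c.last, c.votes) for c in got] == want

    def test_vote_long_emits_interval_pairs(self):
        hits = hits_from_deltas([1000, 1010, 1020])
        hits = [
            AdjustedHit(ref_id=0, delta=d, ref_pos=d + rp, read_pos=rp, strand=0)
            for d, rp in [(1000, 0), (1010, 50), (1020, 90)]
        ]
        pairs = vote_long(hits, D=100, V=3, read_len=200, seed_span=38)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.votes == 3
        assert p.ref_begin == 1000
        assert p.ref_end == 1110 + 38
        assert p.read_begin == 0
        assert p.read_end == 90 + 38

    def test_vote_long_threshold_drops_small_clusters(self):
        # three dense clusters pass V=3; two sparse ones are dropped
        deltas = [0, 10, 20, 5000, 9000, 9005, 9010, 9015, 20000]
        pairs = vote_long(hits_from_deltas(deltas), D=100, V=3, read_len=100, seed_span=10)
        assert len(pairs) == 2
        assert {p.votes for p in pairs} == {3, 4}

    def test_single_seed_cluster_v1(self):
        pairs = vote_long(hits_from_deltas([500]), D=100, V=1, read_len=100, seed_span=26)
        assert len(pairs) == 1
        assert pairs[0].ref_end - pairs[0].ref_begin == 26

    def test_increasing_v_never_adds_clusters(self, rng):
        deltas = sorted(rng.integers(0, 3000, size=80).tolist())
        hits = hits_from_deltas(deltas)
        counts = [len(vote_short(hits, D=50, V=v)) for v in range(1, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_increasing_d_never_increases_cluster_count(self, rng):
        deltas = sorted(rng.integers(0, 3000, size=80).tolist())
        hits = hits_from_deltas(deltas)
        counts = [len(vote_short(hits, D=d, V=1)) for d in (10, 50, 200, 1000, 5000)]
        assert counts == sorted(counts, reverse=True)

    def test_cap_truncates(self, rng):
        deltas = sorted(set(rng.integers(0, 100_000, size=100).tolist()))
        assert len(vote_short(hits_from_deltas(deltas), D=1, V=1, cap=5)) == 5


class TestRescue:
    def test_best_cluster_below_threshold(self):
        clusters = _cluster(hits_from_deltas([0, 1, 500]), 100, 0)
        best = rescue_location(clusters)
        assert best.votes == 2
        assert best.anchor == 0

    def test_tie_breaks_to_smallest_delta(self):
        clusters = _cluster(hits_from_deltas([500, 1500]), 100, 0)
        assert rescue_location(clusters).anchor == 500

    def test_no_hits_reports_unmapped(self):
        assert rescue_location([]) is None

    def test_rescue_equals_oracle_max(self, rng):
        deltas = sorted(rng.integers(0, 5000, size=40).tolist())
        D = 80
        best = rescue_location(_cluster(hits_from_deltas(deltas), D, 0))
        oracle = min(cluster_oracle(deltas, D), key=lambda t: (-t[2], t[0]))
        assert (best.anchor, best.votes) == (oracle[0], oracle[2])


class TestSegmentation:
    def test_65kb_read(self):
        read = "A" * 65_000
        segs = segment_ultralong(read)
        assert [len(s) for _, s in segs] == [30_000, 30_000, 5_000]
        assert [o for o, _ in segs] == [0, 30_000, 60_000]

    def test_short_read_single_segment(self):
        assert segment_ultralong("ACGT") == [(0, "ACGT")]

    def test_concatenation_identity(self, rng):
        read = random_dna(rng, 70_123)
        segs = segment_ultralong(read)
        assert "".join(s for _, s in segs) == read


class TestStrandGeometry:
    def test_reverse_strand_read_clusters_at_origin(self, small_genome, small_index):
        seq = small_genome[1]
        o = 20_000
        read = revcomp(seq[o : o + 1000])
        a = pattern_align(read, small_index.pattern, small_index)
        ms = compressed_seed(read, small_index.pattern, a, 19, 16)
        fwd, rev = adjust_and_sort_hits(ms, small_index, len(read))
        clusters = vote_short(rev, D=150, V=2, strand=1)
        assert clusters, "reverse-strand read produced no winning cluster"
        assert abs(clusters[0].anchor - o) < 100
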