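"""Banded DP alignment, CIGAR handling, classification, MAPQ, SAM output."""

import io

import numpy as np
import pytest

from dietmap import (
    MappingRecord,
    ScoringScheme,
    banded_global_align,
    banded_local_align,
    classify_alignments,
    compute_mapq,
    concat_pair_cigars,
    exact_match_filter,
    write_sam,
)
from dietmap.align import AlignmentResult, OP_D, OP_I, OP_M, sam_flag

from _helpers import cigar_score, codes, full_affine_score, random_dna

SC = ScoringScheme()  # match 2, mismatch 4, gap open 4, extend 2


class TestExactFilter:
    def test_identical(self):
        assert exact_match_filter("ACGT" * 30, "ACGT" * 30)

    def test_single_substitution(self):
        a = "ACGT" * 30
        b = a[:50] + "T" + a[51:]
        assert b != a
        assert not exact_match_filter(a, b)

    def test_agrees_with_characterwise_comparison(self, rng):
        for _ in range(20):
            a = random_dna(rng, 80)
            b = list(a)
            if rng.random() < 0.5:
                i = int(rng.integers(0, 80))
                b[i] = "ACGT"[("ACGT".index(b[i]) + 1) % 4]
            b = "".join(b)
            assert exact_match_filter(a, b) == all(x == y for x, y in zip(a, b))

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError):
            exact_match_filter("ACGT", "ACG")


class TestGlobalAlign:
    def test_identical_sequences(self, rng):
        seq = random_dna(rng, 120)
        res = banded_global_align(seq, seq, SC, band=8)
        assert res.score == SC.match * 120
        assert res.cigar == "120M"
        res.validate()

    def test_single_mismatch(self, rng):
        a = random_dna(rng, 100)
        b = a[:40] + ("A" if a[40] != "A" else "C") + a[41:]
        res = banded_global_align(b, a, SC, band=8)
        assert res.score == SC.match * 99 - SC.mismatch
        assert res.nm == 1

    def test_wide_band_equals_full_dp(self, rng):
        # random pairs <= 200 bases, including indel-mutated copies
        for trial in range(100):
            n = int(rng.integers(20, 200))
            a = random_dna(rng, n)
            if trial % 2 == 0:
                b = random_dna(rng, int(rng.integers(20, 200)))
            else:  # mutated copy with an indel
                cut = int(rng.integers(1, n - 5))
                b = a[:cut] + random_dna(rng, int(rng.integers(0, 6))) + a[cut + int(rng.integers(0, 4)):]
            band = len(a) + len(b)
            res = banded_global_align(a, b, SC, band=band)
            want = full_affine_score(
                codes(a), codes(b), SC.match, SC.mismatch, SC.gap_open, SC.gap_extend, False
            )
            assert res.score == want
            # the CIGAR must reproduce the reported score over the sequences
            assert cigar_score(
                res.cigar, a, b, res.read_begin, res.ref_begin,
                SC.match, SC.mismatch, SC.gap_open, SC.gap_extend,
            ) == res.score - _trimmed_gap_penalty(res, len(b))
            res.validate()

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            banded_global_align("", "ACGT", SC, band=4)


def _trimmed_gap_penalty(res, ref_len):
    """Boundary deletions are trimmed from the CIGAR but still paid in the
    global score; account for them when re-scoring the CIGAR."""
    lead = res.ref_begin
    trail = ref_len - res.ref_end
    pen = 0
    if lead:
        pen -= SC.gap_open + SC.gap_extend * lead
    if trail:
        pen -= SC.gap_open + SC.gap_extend * trail
    return pen


class TestLocalAlign:
    def test_embedded_exact_50mer(self, rng):
        core = random_dna(rng, 50)
        ref = random_dna(rng, 100) + core + random_dna(rng, 100)
        res = banded_local_align(core, ref, SC, band=len(ref))
        assert res.score == SC.match * 50
        assert res.read_end - res.read_begin == 50
        res.validate()

    def test_unrelated_pairs_score_near_null(self, rng):
        scores = []
        for _ in range(20):
            a = random_dna(rng, 100)
            b = random_dna(rng, 100)
            scores.append(banded_local_align(a, b, SC, band=200).score)
        # random 100-mers share only short chance matches
        assert np.median(scores) < 0.3 * SC.match * 100

    def test_wide_band_equals_full_dp(self, rng):
        for _ in range(50):
            a = random_dna(rng, int(rng.integers(20, 150)))
            b = random_dna(rng, int(rng.integers(20, 150)))
            res = banded_local_align(a, b, SC, band=len(a) + len(b))
            want = full_affine_score(
                codes(a), codes(b), SC.match, SC.mismatch, SC.gap_open, SC.gap_extend, True
            )
            assert res.score == want
            res.validate()


class TestConcat:
    def _result(self, score, rb, re_, gb, ge, n_match):
        ops = [(OP_M, n_match)]
        return AlignmentResult(
            score=score, cigar=f"{n_match}M", ref_begin=gb, ref_end=ge,
            read_begin=rb, read_end=re_, matches=n_match, ops=ops,
        )

    def test_clean_deletion_bridged(self, rng):
        # two pairs separated by a 500-base reference gap -> single CIGAR with 500D
        read = random_dna(rng, 200)
        ref = read[:100] + random_dna(rng, 500) + read[100:]
        r1 = self._result(200, 0, 100, 0, 100, 100)
        r2 = self._result(200, 100, 200, 600, 700, 100)
        merged = concat_pair_cigars([r1, r2], read, ref, SC, band=32)
        assert len(merged) == 1
        assert "500D" in merged[0].cigar
        merged[0].validate()

    def test_distant_pairs_stay_separate(self, rng):
        read = random_dna(rng, 200)
        ref = random_dna(rng, 61_000)
        r1 = self._result(200, 0, 100, 0, 100, 100)
        r2 = self._result(200, 100, 200, 60_100, 60_200, 100)
        merged = concat_pair_cigars([r1, r2], read, ref, SC, band=32)
        assert len(merged) == 2

    def test_merged_score_bounded_below(self, rng):
        # merged score >= sum of part scores minus the bridge gap penalty
        for _ in range(10):
            read = random_dna(rng, 300)
            gap = int(rng.integers(1, 40))
            ref = read[:150] + random_dna(rng, gap) + read[150:]
            r1 = self._result(300, 0, 150, 0, 150, 150)
            r2 = self._result(300, 150, 300, 150 + gap, 300 + gap, 150)
            merged = concat_pair_cigars([r1, r2], read, ref, SC, band=64)
            assert len(merged) == 1
            floor = r1.score + r2.score - (SC.gap_open + SC.gap_extend * gap)
            assert merged[0].score >= floor
            merged[0].validate()

    def test_overlapping_read_intervals_keep_better(self, rng):
        read = random_dna(rng, 100)
        ref = random_dna(rng, 1000)
        weak = self._result(50, 0, 80, 0, 80, 40)
        strong = self._result(160, 20, 100, 500, 580, 80)
        merged = concat_pair_cigars([weak, strong], read, ref, SC, band=16)
        assert len(merged) == 1
        assert merged[0].score == 160


class TestClassify:
    def _res(self, score, length):
        return AlignmentResult(
            score=score, cigar=f"{length}M", ref_begin=0, ref_end=length,
            read_begin=0, read_end=length, ops=[(OP_M, length)],
        )

    def test_single_result_primary(self):
        assert classify_alignments([self._res(100, 100)]) == ["primary"]

    def test_half_length_is_supplementary(self):
        cats = classify_alignments([self._res(200, 100), self._res(80, 50)])
        assert cats == ["primary", "supplementary"]

    def test_near_full_length_is_secondary(self):
        cats = classify_alignments([self._res(200, 100), self._res(150, 95)])
        assert cats == ["primary", "secondary"]


class TestMapq:
    def test_unique_perfect_hit_is_60(self):
        assert compute_mapq(300, 0, 12, 1.0) == 60

    def test_equal_candidates_capped_at_20(self):
        assert compute_mapq(300, 300, 12, 1.0) <= 20

    def test_monotone_in_score_gap(self):
        qs = [compute_mapq(300, s, 12, 0.9) for s in range(300, -1, -30)]
        assert qs == sorted(qs)

    def test_clamped_to_range(self):
        assert 0 <= compute_mapq(1, 0, 1, 0.0) <= 60
        assert compute_mapq(0, 0, 0, 0.0) == 0


class TestSamOutput:
    def _records(self):
        return [
            MappingRecord(
                read_name="r1", flag=sam_flag("primary", 0), ref_name="chr1", pos=101,
                mapq=60, cigar="50M", category="primary", seq="A" * 50, nm=0, score=100,
            ),
            MappingRecord(
                read_name="r2", flag=sam_flag("primary", 1), ref_name="chr1", pos=5,
                mapq=30, cigar="10S40M", category="primary", seq="C" * 50, nm=2, score=60,
            ),
            MappingRecord(
                read_name="r3", flag=4, ref_name="*", pos=0, mapq=0, cigar="*",
                category="unmapped", seq="G" * 20,
            ),
        ]

    def test_flags(self):
        buf = io.StringIO()
        write_sam(self._records(), ["chr1"], [10_000], buf)
        lines = [l for l in buf.getvalue().splitlines() if not l.startswith("@")]
        flags = [int(l.split("\t")[1]) for l in lines]
        assert flags == [0, 16, 4]

    def test_parses_with_pysam_and_roundtrips_coordinates(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        path = tmp_path / "out.sam"
        with open(path, "w") as fh:
            write_sam(self._records(), ["chr1"], [10_000], fh)
        with pysam.AlignmentFile(str(path)) as sam:
            recs = list(sam)
        assert [r.query_name for r in recs] == ["r1", "r2", "r3"]
        assert recs[0].reference_start == 100  # SAM 1-based -> pysam 0-based
        assert recs[1].is_reverse
        assert recs[2].is_unmapped
        assert recs[1].cigarstring == "10S40M"

    def test_unknown_reference_rejected(self):
        rec = MappingRecord(
            read_name="r", flag=0, ref_name="nope", pos=1, mapq=0, cigar="5M",
            category="primary", seq="ACGTA",
        )
        with pytest.raises(ValueError, match="unknown reference"):
            write_sam([rec], ["chr1"], [100], io.StringIO())
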