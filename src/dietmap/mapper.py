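"""End-to-end read mapping: phase selection, voting, alignment, records.

Mode presets (the voting thresholds are user-tunable; these defaults follow
common short/long-read practice):

======== ===================== === ==========================
mode     D (max vote distance) V   alignment
======== ===================== === ==========================
sr       0.1 * read_len + 50   2   global (whole read)
map-hifi 500                   3   local per subsequence pair
map-ont  1000                  3   local per subsequence pair
======== ===================== === ==========================

Ultra-long reads are processed in segments of at most 30,000 bases each and
the per-segment candidates are lifted back to whole-read coordinates before
CIGAR concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator

from .align import (
    OP_M,
    OP_S,
    AlignmentResult,
    MappingRecord,
    ScoringScheme,
    banded_global_align,
    banded_local_align,
    cigar_text,
    classify_alignments,
    compute_mapq,
    concat_pair_cigars,
    default_band,
    exact_match_filter,
    revcomp,
    sam_flag,
)
from .index import SeedIndex
from .mapping import (
    PatternAlignConfig,
    SubsequencePair,
    _cluster,
    adjust_and_sort_hits,
    cluster_to_pair,
    compressed_seed,
    pattern_align,
    rescue_location,
    seed_span_bases,
    segment_ultralong,
)

__all__ = ["MapperConfig", "ReadMapper"]

LONG_MODES = {"map-hifi", "map-ont"}


@dataclass
class MapperConfig:
    mode: str = "sr"
    D: int | None = None  # None: per-mode default
    V: int | None = None
    t: int = 10
    cap: int = 50
    align_candidates: int = 5
    scoring: ScoringScheme = ScoringScheme()
    do_align: bool = True
    rescue: bool = True
    seg_limit: int = 30_000

    def __post_init__(self):
        if self.mode not in {"sr"} | LONG_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")

    def vote_distance(self, read_len: int) -> int:
        if self.D is not None:
            return self.D
        if self.mode == "sr":
            return int(round(0.1 * read_len)) + 50
        return 500 if self.mode == "map-hifi" else 1000

    @property
    def vote_threshold(self) -> int:
        if self.V is not None:
            return self.V
        return 2 if self.mode == "sr" else 3


class ReadMapper:
    """Maps reads against a :class:`SeedIndex` built with the same pattern,
    k, and w."""

    def __init__(self, index: SeedIndex, config: MapperConfig | None = None, **kw):
        self.index = index
        self.config = config or MapperConfig(**kw)
        if self.config.do_align and index.sequences is None:
            raise ValueError(
                "index was built without sequences; alignment unavailable "
                "(rebuild with keep_sequences=True or disable alignment)"
            )
        self._pa_cfg = PatternAlignConfig(t=self.config.t)
        self._span = seed_span_bases(index.pattern, index.k)

    # ------------------------------------------------------------------
    def map_read(self, name: str, seq: str) -> list[MappingRecord]:
        seq = seq.upper()
        if self.config.mode == "sr":
            return self._map_short(name, seq)
        return self._map_long(name, seq)

    def map_reads(
        self, reads: Iterable[tuple[str, str]]
    ) -> Iterator[MappingRecord]:
        for name, seq in reads:
            yield from self.map_read(name, seq)

    # ------------------------------------------------------------------
    def _candidates(self, seq: str, D: int):
        """Pattern-align, seed, and cluster one sequence.

        Returns (winning clusters sorted by votes, all clusters)."""
        idx = self.index
        cfg = self.config
        a = pattern_align(seq, idx.pattern, idx, self._pa_cfg)
        ms = compressed_seed(seq, idx.pattern, a, idx.k, idx.w)
        fwd, rev = adjust_and_sort_hits(ms, idx, len(seq))
        clusters = _cluster(fwd, D, 0) + _cluster(rev, D, 1)
        winners = sorted(
            (c for c in clusters if c.votes >= cfg.vote_threshold),
            key=lambda c: (-c.votes, c.anchor),
        )[: cfg.cap]
        return winners, clusters

    def _unmapped(self, name: str, seq: str) -> list[MappingRecord]:
        return [
            MappingRecord(
                read_name=name,
                flag=4,
                ref_name="*",
                pos=0,
                mapq=0,
                cigar="*",
                category="unmapped",
                seq=seq,
            )
        ]

    # ------------------------------------------------------------------
    def _map_short(self, name: str, seq: str) -> list[MappingRecord]:
        cfg = self.config
        read_len = len(seq)
        if read_len < self.index.k:
            return self._unmapped(name, seq)
        D = cfg.vote_distance(read_len)
        winners, clusters = self._candidates(seq, D)
        if not winners and cfg.rescue:
            best = rescue_location(clusters)
            winners = [best] if best is not None else []
        if not winners:
            return self._unmapped(name, seq)
        if not cfg.do_align:
            return self._vote_only_records(name, seq, winners, read_len)

        results: list[AlignmentResult] = []
        meta: list[tuple[int, int, int]] = []  # (ref_id, strand, ref_offset)
        for c in winners[: cfg.align_candidates]:
            ref_seq = self.index.sequences[c.ref_id]
            oriented = seq if c.strand == 0 else revcomp(seq)
            start = max(0, c.anchor)
            end = min(len(ref_seq), start + read_len + c.distance)
            if end - start < 1:
                continue
            seg = ref_seq[start:end]
            if len(seg) == read_len and exact_match_filter(oriented, seg):
                res = AlignmentResult(
                    score=cfg.scoring.match * read_len,
                    cigar=f"{read_len}M",
                    ref_begin=0,
                    ref_end=read_len,
                    read_begin=0,
                    read_end=read_len,
                    matches=read_len,
                    nm=0,
                    votes=c.votes,
                    ops=[(OP_M, read_len)],
                )
            else:
                band = default_band(c.distance, read_len)
                res = banded_global_align(oriented, seg, cfg.scoring, band)
                res.votes = c.votes
            res.ref_begin += start
            res.ref_end += start
            results.append(res)
            meta.append((c.ref_id, c.strand, 0))
        return self._emit(name, seq, results, meta)

    # ------------------------------------------------------------------
    def _map_long(self, name: str, seq: str) -> list[MappingRecord]:
        cfg = self.config
        read_len = len(seq)
        if read_len < self.index.k:
            return self._unmapped(name, seq)
        D = cfg.vote_distance(read_len)
        V = cfg.vote_threshold

        pairs: list[SubsequencePair] = []
        any_hits = False
        segments = segment_ultralong(seq, cfg.seg_limit) if read_len > cfg.seg_limit else [(0, seq)]
        for off, segment in segments:
            slen = len(segment)
            if slen < self.index.k:
                continue
            winners, clusters = self._candidates(segment, D)
            if clusters:
                any_hits = True
            if not winners and cfg.rescue:
                best = rescue_location(clusters)
                winners = [best] if best is not None else []
            for c in winners[: cfg.align_candidates]:
                ref_len = int(self.index.lengths[c.ref_id])
                pair = cluster_to_pair(c, self._span, slen, ref_len)
                # lift segment-local read coordinates to whole-read coords
                # (reverse-strand coords live on the reverse-complemented read)
                if c.strand == 0:
                    shift = off
                else:
                    shift = read_len - off - slen
                pair.read_begin += shift
                pair.read_end += shift
                pair.bound_lo = shift
                pair.bound_hi = shift + slen
                pairs.append(pair)
        if not pairs:
            return self._unmapped(name, seq) if not any_hits else self._unmapped(name, seq)
        if not cfg.do_align:
            return self._pair_records(name, seq, pairs, read_len)

        # align each pair locally, grouped by (ref_id, strand)
        groups: dict[tuple[int, int], list[AlignmentResult]] = {}
        oriented_cache: dict[int, str] = {}
        for pair in pairs:
            ref_seq = self.index.sequences[pair.ref_id]
            oriented = oriented_cache.setdefault(
                pair.strand, seq if pair.strand == 0 else revcomp(seq)
            )
            # pad outward by the expected seed spacing so the local alignment
            # can reach read ends that lie before the first / after the last seed
            flank = self._span + int((self.index.w + 1) * self.index.pattern.beta)
            lo = pair.bound_lo
            hi = pair.bound_hi if pair.bound_hi is not None else read_len
            rb = max(lo, pair.read_begin - flank)
            re_ = min(hi, pair.read_end + flank)
            gb = max(0, pair.ref_begin - (pair.read_begin - rb))
            ge = min(len(ref_seq), pair.ref_end + (re_ - pair.read_end))
            read_sub = oriented[rb:re_]
            ref_sub = ref_seq[gb:ge]
            if not read_sub or not ref_sub:
                continue
            if len(read_sub) == len(ref_sub) and read_sub == ref_sub:
                n = len(read_sub)
                res = AlignmentResult(
                    score=cfg.scoring.match * n,
                    cigar=f"{n}M",
                    ref_begin=gb,
                    ref_end=ge,
                    read_begin=rb,
                    read_end=re_,
                    matches=n,
                    nm=0,
                    votes=pair.votes,
                    ops=[(OP_M, n)],
                )
            else:
                band = default_band(pair.distance, len(read_sub))
                res = banded_local_align(read_sub, ref_sub, cfg.scoring, band)
                if res.read_end == res.read_begin:
                    continue
                res.votes = pair.votes
                res.ref_begin += gb
                res.ref_end += gb
                res.read_begin += rb
                res.read_end += rb
            groups.setdefault((pair.ref_id, pair.strand), []).append(res)

        results: list[AlignmentResult] = []
        meta: list[tuple[int, int, int]] = []
        for (rid, strand), group in groups.items():
            oriented = oriented_cache[strand]
            ref_seq = self.index.sequences[rid]
            for res in concat_pair_cigars(group, oriented, ref_seq, cfg.scoring):
                results.append(res)
                meta.append((rid, strand, 0))
        return self._emit(name, seq, results, meta)

    # ------------------------------------------------------------------
    def _emit(
        self,
        name: str,
        seq: str,
        results: list[AlignmentResult],
        meta: list[tuple[int, int, int]],
    ) -> list[MappingRecord]:
        if not results:
            return self._unmapped(name, seq)
        cats = classify_alignments(results)
        order = sorted(range(len(results)), key=lambda i: -results[i].score)
        best = results[order[0]]
        second_score = results[order[1]].score if len(order) > 1 else 0
        mapq = compute_mapq(best.score, second_score, best.votes, best.identity)
        read_len = len(seq)
        records = []
        for res, cat, (rid, strand, _) in zip(results, cats, meta):
            ops = list(res.ops)
            lead = res.read_begin
            trail = read_len - res.read_end
            if lead:
                ops = [(OP_S, lead)] + ops
            if trail:
                ops = ops + [(OP_S, trail)]
            oriented = seq if strand == 0 else revcomp(seq)
            records.append(
                MappingRecord(
                    read_name=name,
                    flag=sam_flag(cat, strand),
                    ref_name=self.index.names[rid],
                    pos=res.ref_begin + 1,
                    mapq=mapq if cat == "primary" else 0,
                    cigar=cigar_text(ops),
                    category=cat,
                    seq=oriented,
                    score=res.score,
                    votes=res.votes,
                    nm=res.nm,
                    ref_id=rid,
                    strand=strand,
                )
            )
        records.sort(key=lambda r: (r.category != "primary", -r.score))
        return records

    # vote-only outputs (alignment disabled, e.g. containment search) -----
    def _vote_only_records(self, name, seq, winners, read_len) -> list[MappingRecord]:
        records = []
        for i, c in enumerate(winners):
            cat = "primary" if i == 0 else "secondary"
            pos = max(0, c.anchor)
            records.append(
                MappingRecord(
                    read_name=name,
                    flag=sam_flag(cat, c.strand),
                    ref_name=self.index.names[c.ref_id],
                    pos=pos + 1,
                    mapq=0,
                    cigar=f"{read_len}M",
                    category=cat,
                    seq=seq,
                    score=0,
                    votes=c.votes,
                    ref_id=c.ref_id,
                    strand=c.strand,
                )
            )
        return records

    def _pair_records(self, name, seq, pairs, read_len) -> list[MappingRecord]:
        pairs = sorted(pairs, key=lambda p: -p.votes)
        records = []
        for i, p in enumerate(pairs):
            cat = "primary" if i == 0 else "secondary"
            records.append(
                MappingRecord(
                    read_name=name,
                    flag=sam_flag(cat, p.strand),
                    ref_name=self.index.names[p.ref_id],
                    pos=max(0, p.ref_begin) + 1,
                    mapq=0,
                    cigar="*",
                    category=cat,
                    seq=seq,
                    score=0,
                    votes=p.votes,
                    ref_id=p.ref_id,
                    strand=p.strand,
                )
            )
        return records
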