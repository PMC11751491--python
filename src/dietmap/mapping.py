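"""Per-read seeding and location voting.

For each read the mapper must first recover the *pattern phase*: the
reference was sparsified starting at its first base, but a read sampled at an
unknown offset ``o`` only matches the index when its own mask is shifted by
``a ≡ o (mod p)``.  The pattern-alignment step tries all ``p`` shifts,
sketches a capped number of minimizers per shifted read, and picks the shift
whose seeds have the highest summed occurrence in the index.

Matching locations are then *adjusted* (reference position minus read
position), merged into one sorted stream per reference/strand, and clustered
by a greedy left-to-right scan: deltas within a user distance ``D`` of the
cluster anchor vote for the same mapping location, and clusters with at least
``V`` votes win.  This replaces seed chaining entirely — sparsified seeds are
not exact anchors, so chain scoring is not applicable, while vote counting
is.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Sequence

import numpy as np

from .index import SeedIndex
from .pattern import DietPattern, apply_pattern
from .sketch import MinimizerSet, extract_minimizers

__all__ = [
    "PatternAlignConfig",
    "AdjustedHit",
    "VoteCluster",
    "SubsequencePair",
    "pattern_align",
    "compressed_seed",
    "adjust_and_sort_hits",
    "vote_short",
    "vote_long",
    "rescue_location",
    "segment_ultralong",
]


@dataclass(frozen=True)
class PatternAlignConfig:
    """Caps for the pattern-alignment step.

    ``t`` limits the number of minimizers considered per shifted read;
    frequency exclusion mirrors the index's ``max_occ`` (hyper-frequent seeds
    contribute 0 to the per-shift sums so they cannot dominate the count).
    """

    t: int = 10

    def __post_init__(self):
        if self.t < 1:
            raise ValueError("t must be >= 1")


@dataclass(frozen=True)
class AdjustedHit:
    """One seed match, keyed by ``delta = ref_pos - read_pos``."""

    ref_id: int
    delta: int
    ref_pos: int
    read_pos: int
    strand: int  # 0 = forward match, 1 = reverse match


@dataclass
class VoteCluster:
    anchor: int  # Δ0: first delta of the cluster
    last: int  # ΔD: last delta that joined (last - anchor <= D)
    votes: int
    ref_id: int
    strand: int
    ref_lo: int = 0  # smallest implicated reference position
    ref_hi: int = 0  # largest implicated reference position
    read_lo: int = 0
    read_hi: int = 0

    @property
    def distance(self) -> int:
        return self.last - self.anchor


@dataclass
class SubsequencePair:
    ref_id: int
    strand: int
    ref_begin: int
    ref_end: int
    read_begin: int
    read_end: int
    votes: int
    anchor: int = 0
    distance: int = 0
    # read-coordinate bounds the pair may be padded within (segment limits)
    bound_lo: int = 0
    bound_hi: int | None = None


def pattern_align(
    read_seq: str,
    pattern: DietPattern,
    idx: SeedIndex,
    cfg: PatternAlignConfig = PatternAlignConfig(),
) -> int:
    """Choose the pattern shift (alignment index ``a``) for *read_seq*.

    For each shift ``s`` in ``[0, p)`` the read is sparsified at that shift,
    at most ``t`` minimizers are taken from its prefix, and their occurrence
    counts in the index are summed (per occurrence; hyper-frequent seeds count
    0).  Returns the shift with the highest sum; ties break to the smallest
    shift, and 0 is returned when every sum is zero.
    """
    best_s, best_sum = 0, 0
    for s in range(pattern.p):
        ps = apply_pattern(pattern, s, read_seq)
        ms = extract_minimizers(ps, idx.k, idx.w)
        total = 0
        for h in ms.hashes[: cfg.t]:
            total += idx.occurrence(int(h))
        if total > best_sum:
            best_s, best_sum = s, total
    return best_s


def compressed_seed(
    read_seq: str, pattern: DietPattern, a: int, k: int, w: int
) -> MinimizerSet:
    """Minimizers of the read sparsified at shift ``a`` (original read
    coordinates)."""
    ps = apply_pattern(pattern, a, read_seq)
    return extract_minimizers(ps, k, w)


def adjust_and_sort_hits(
    read_minis: MinimizerSet, idx: SeedIndex, read_len: int
) -> tuple[list[AdjustedHit], list[AdjustedHit]]:
    """Query the index for each read minimizer and merge the per-seed sorted
    location lists into one ``(ref_id, delta)``-sorted stream per strand.

    A match is *forward* when the reference and read seeds were canonicalized
    on the same strand and *reverse* otherwise; reverse-strand read positions
    are measured from the read's reverse complement (position of the seed's
    last covered base from the 3' end), so deltas stay additive on both
    strands.  Duplicate ``(delta, ref_pos, read_pos)`` triples are kept once.
    """
    runs: tuple[list, list] = ([], [])
    for i in range(len(read_minis)):
        refs, poss, strands, _spans = idx.query(int(read_minis.hashes[i]))
        if len(refs) == 0:
            continue
        rpos = int(read_minis.positions[i])
        rspan = int(read_minis.spans[i])
        rstrand = int(read_minis.strands[i])
        rpos_rc = read_len - rpos - rspan
        # per-seed lists are sorted by (ref_id, position) == (ref_id, delta)
        fwd_run, rev_run = [], []
        for rid, pos, st in zip(refs.tolist(), poss.tolist(), strands.tolist()):
            if st == rstrand:
                fwd_run.append((rid, pos - rpos, pos, rpos))
            else:
                rev_run.append((rid, pos - rpos_rc, pos, rpos_rc))
        if fwd_run:
            runs[0].append(fwd_run)
        if rev_run:
            runs[1].append(rev_run)

    out: list[list[AdjustedHit]] = [[], []]
    for strand in (0, 1):
        merged = heapq.merge(*runs[strand])
        prev = None
        for rid, delta, pos, rpos in merged:
            key = (rid, delta, pos, rpos)
            if key == prev:
                continue
            prev = key
            out[strand].append(
                AdjustedHit(ref_id=rid, delta=delta, ref_pos=pos, read_pos=rpos, strand=strand)
            )
    return out[0], out[1]


def _cluster(hits: Sequence[AdjustedHit], D: int, strand: int) -> list[VoteCluster]:
    """Greedy left-to-right clustering of delta-sorted hits of one strand.

    The first delta opens a cluster (anchor Δ0); every following hit on the
    same reference with ``delta - Δ0 <= D`` joins and votes; the first hit
    beyond ``D`` (or on a new reference) opens the next cluster.
    """
    clusters: list[VoteCluster] = []
    cur: VoteCluster | None = None
    for h in hits:
        if cur is not None and h.ref_id == cur.ref_id and h.delta - cur.anchor <= D:
            cur.votes += 1
            cur.last = h.delta
            cur.ref_lo = min(cur.ref_lo, h.ref_pos)
            cur.ref_hi = max(cur.ref_hi, h.ref_pos)
            cur.read_lo = min(cur.read_lo, h.read_pos)
            cur.read_hi = max(cur.read_hi, h.read_pos)
        else:
            cur = VoteCluster(
                anchor=h.delta,
                last=h.delta,
                votes=1,
                ref_id=h.ref_id,
                strand=strand,
                ref_lo=h.ref_pos,
                ref_hi=h.ref_pos,
                read_lo=h.read_pos,
                read_hi=h.read_pos,
            )
            clusters.append(cur)
    return clusters


def _rank(clusters: Iterable[VoteCluster]) -> list[VoteCluster]:
    return sorted(clusters, key=lambda c: (-c.votes, c.anchor))


def vote_short(
    hits: Sequence[AdjustedHit], D: int, V: int, cap: int = 50, strand: int = 0
) -> list[VoteCluster]:
    """Short-read voting: clusters with ``votes >= V``, best first, at most
    *cap* clusters."""
    winners = [c for c in _cluster(hits, D, strand) if c.votes >= V]
    return _rank(winners)[:cap]


def vote_long(
    hits: Sequence[AdjustedHit],
    D: int,
    V: int,
    cap: int = 50,
    read_len: int = 0,
    seed_span: int = 0,
    strand: int = 0,
    ref_len: int | None = None,
) -> list[SubsequencePair]:
    """Long-read voting: each winning cluster becomes a subsequence pair.

    The reference interval spans from the smallest implicated reference
    position to the largest plus the pattern-span of a seed (``k * beta``),
    and the read interval covers the corresponding read positions.
    """
    pairs = []
    for c in _rank([c for c in _cluster(hits, D, strand) if c.votes >= V])[:cap]:
        pairs.append(cluster_to_pair(c, seed_span, read_len, ref_len))
    return pairs


def cluster_to_pair(
    c: VoteCluster, seed_span: int, read_len: int, ref_len: int | None = None
) -> SubsequencePair:
    ref_end = c.ref_hi + seed_span
    read_end = c.read_hi + seed_span
    if ref_len is not None:
        ref_end = min(ref_end, ref_len)
    if read_len:
        read_end = min(read_end, read_len)
    return SubsequencePair(
        ref_id=c.ref_id,
        strand=c.strand,
        ref_begin=c.ref_lo,
        ref_end=ref_end,
        read_begin=c.read_lo,
        read_end=read_end,
        votes=c.votes,
        anchor=c.anchor,
        distance=c.distance,
    )


def rescue_location(all_clusters: Sequence[VoteCluster]) -> VoteCluster | None:
    """Single best-voted cluster regardless of the vote threshold.

    Used when no cluster reaches ``V`` so the read is not lost outright;
    ties on votes break to the smallest delta.  Returns ``None`` when there
    were no hits at all (read reported unmapped).
    """
    if not all_clusters:
        return None
    return min(all_clusters, key=lambda c: (-c.votes, c.anchor))


def segment_ultralong(read_seq: str, limit: int = 30_000) -> list[tuple[int, str]]:
    """Split an ultra-long read into consecutive ``(offset, segment)`` pieces
    of at most *limit* bases; their concatenation reproduces the read."""
    if limit < 1:
        raise ValueError("limit must be >= 1")
    return [(off, read_seq[off : off + limit]) for off in range(0, max(len(read_seq), 1), limit)]


def seed_span_bases(pattern: DietPattern, k: int) -> int:
    """Original bases covered by one patterned k-mer: ``ceil(k * beta)``."""
    return ceil(k * pattern.beta)
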