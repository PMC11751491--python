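"""Base-level alignment of winning candidates and SAM/PAF emission.

Short reads are aligned globally (Needleman–Wunsch, affine gaps) against the
reference segment implied by their winning vote cluster; long-read
subsequence pairs are aligned locally (Smith–Waterman).  Both kernels are
*banded*: the voting distance of a cluster bounds how far matching seeds
drifted apart, so it serves as the DP band width (plus a safety margin),
which keeps alignment linear in read length in practice.  A wide enough band
reproduces the unbanded optimum exactly.

MAPQ here is a documented deterministic surrogate combining the best/second
score gap, the vote count, and the identity of the primary alignment (the
header carries a comment flagging it as such).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Sequence, TextIO

import numpy as np
from numba import njit

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "MappingRecord",
    "exact_match_filter",
    "banded_global_align",
    "banded_local_align",
    "concat_pair_cigars",
    "classify_alignments",
    "compute_mapq",
    "write_sam",
    "write_paf",
    "default_band",
]

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = str.maketrans("ACGTN", "TGCAN")

OP_M, OP_I, OP_D, OP_S = 0, 1, 2, 3
_OP_CHARS = "MIDS"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _codes(seq: str) -> np.ndarray:
    return np.fromiter((_ENC.get(c, 4) for c in seq.upper()), dtype=np.int8, count=len(seq))


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring; mismatch/gap values are penalties (>= 0)."""

    match: int = 2
    mismatch: int = 4
    gap_open: int = 4
    gap_extend: int = 2

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be >= 0")


@dataclass
class AlignmentResult:
    score: int
    cigar: str
    ref_begin: int
    ref_end: int
    read_begin: int
    read_end: int
    matches: int = 0
    nm: int = 0  # mismatches + gap bases
    votes: int = 0
    ops: list[tuple[int, int]] = field(default_factory=list)  # (op, length)

    @property
    def identity(self) -> float:
        aligned = sum(n for _, n in self.ops)
        return self.matches / aligned if aligned else 0.0

    def validate(self) -> None:
        """CIGAR must consume exactly the read and reference intervals."""
        read_len = sum(n for op, n in self.ops if op in (OP_M, OP_I))
        ref_len = sum(n for op, n in self.ops if op in (OP_M, OP_D))
        if read_len != self.read_end - self.read_begin:
            raise ValueError(
                f"CIGAR consumes {read_len} read bases, interval is "
                f"{self.read_end - self.read_begin}"
            )
        if ref_len != self.ref_end - self.ref_begin:
            raise ValueError(
                f"CIGAR consumes {ref_len} ref bases, interval is "
                f"{self.ref_end - self.ref_begin}"
            )


@dataclass
class MappingRecord:
    read_name: str
    flag: int
    ref_name: str
    pos: int  # 1-based leftmost mapping position (0 when unmapped)
    mapq: int
    cigar: str
    category: str  # primary | secondary | supplementary | unmapped
    seq: str = "*"
    score: int = 0
    votes: int = 0
    nm: int = 0
    ref_id: int = -1
    strand: int = 0


# ---------------------------------------------------------------------------
# DP kernels (banded, affine gaps).  Band geometry: cell (i, j) is allowed
# when |j - i| <= band + |n - m|, which always keeps (m, n) reachable.
# ---------------------------------------------------------------------------

_NEG = -(1 << 40)


@njit(cache=True)
def _affine_banded(a, b, match, mis, go, ge, band, local):  # pragma: no cover
    m = a.shape[0]
    n = b.shape[0]
    bw = band + (n - m if n >= m else m - n)
    W = 2 * bw + 1
    H = np.full((m + 1, W), _NEG, np.int64)
    E = np.full((m + 1, W), _NEG, np.int64)
    F = np.full((m + 1, W), _NEG, np.int64)
    # P bits: 0-1 H source (0 diag, 1 E, 2 F, 3 local start), 2 E-extend, 3 F-extend
    P = np.zeros((m + 1, W), np.uint8)
    H[0, bw] = 0
    P[0, bw] = 3
    for j in range(1, min(n, bw) + 1):
        c = j + bw
        E[0, c] = -(go + ge * j)
        if local:
            H[0, c] = 0
            P[0, c] = 3
        else:
            H[0, c] = E[0, c]
            P[0, c] = 1
        if j > 1:
            P[0, c] |= 4
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        jlo = i - bw
        if jlo < 0:
            jlo = 0
        jhi = i + bw
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            c = j - i + bw
            e = _NEG
            eext = False
            if c - 1 >= 0 and j > 0:
                open_e = H[i, c - 1] - go - ge
                ext_e = E[i, c - 1] - ge
                if ext_e > open_e:
                    e = ext_e
                    eext = True
                else:
                    e = open_e
            f = _NEG
            fext = False
            if c + 1 < W:
                open_f = H[i - 1, c + 1] - go - ge
                ext_f = F[i - 1, c + 1] - ge
                if ext_f > open_f:
                    f = ext_f
                    fext = True
                else:
                    f = open_f
            d = _NEG
            if j > 0:
                prev = H[i - 1, c]
                if prev > _NEG // 2:
                    if a[i - 1] == b[j - 1] and a[i - 1] != 4:
                        d = prev + match
                    else:
                        d = prev - mis
            src = np.uint8(0)
            h = d
            if e > h:
                h = e
                src = np.uint8(1)
            if f > h:
                h = f
                src = np.uint8(2)
            if local and h < 0:
                h = 0
                src = np.uint8(3)
            H[i, c] = h
            E[i, c] = e
            F[i, c] = f
            flags = src
            if eext:
                flags |= np.uint8(4)
            if fext:
                flags |= np.uint8(8)
            P[i, c] = flags
            if local and h > best:
                best = h
                bi = i
                bj = j
    if not local:
        bi = m
        bj = n
        best = H[m, n - m + bw]
    # traceback
    ops = np.empty(m + n + 2, np.uint8)
    no = 0
    matches = 0
    nm = 0
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 or j > 0:
        c = j - i + bw
        if state == 0:
            src = P[i, c] & np.uint8(3)
            if local and src == 3:
                break
            if src == 0:
                ops[no] = 0
                no += 1
                if a[i - 1] == b[j - 1] and a[i - 1] != 4:
                    matches += 1
                else:
                    nm += 1
                i -= 1
                j -= 1
            elif src == 1:
                state = 1
            elif src == 2:
                state = 2
            else:
                break
        elif state == 1:
            ops[no] = 2  # D: consumes reference
            no += 1
            nm += 1
            ext = P[i, c] & np.uint8(4)
            j -= 1
            if ext == 0:
                state = 0
        else:
            ops[no] = 1  # I: consumes read
            no += 1
            nm += 1
            ext = P[i, c] & np.uint8(8)
            i -= 1
            if ext == 0:
                state = 0
    return best, ops[:no][::-1].copy(), i, j, bi, bj, matches, nm


def _run_length(ops: np.ndarray) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((int(op), 1))
    return out


def cigar_text(ops: Sequence[tuple[int, int]]) -> str:
    return "".join(f"{n}{_OP_CHARS[op]}" for op, n in ops) or "*"


def _trim_boundary(ops: list[tuple[int, int]], res: "AlignmentResult") -> None:
    """Trim boundary deletions (shift the interval instead) — SAM records
    must not start or end in D."""
    while res.ops and res.ops[0][0] == OP_D:
        res.ref_begin += res.ops[0][1]
        res.ops.pop(0)
    while res.ops and res.ops[-1][0] == OP_D:
        res.ref_end -= res.ops[-1][1]
        res.ops.pop()
    res.cigar = cigar_text(res.ops)


def exact_match_filter(read: str, ref_segment: str) -> bool:
    """True iff the equal-length segments are identical (perfect-match
    fast path: such reads get a ``<len>M`` record without any DP)."""
    if len(read) != len(ref_segment):
        raise ValueError("exact-match filter requires equal-length segments")
    return read.upper() == ref_segment.upper()


def _align(
    read: str, ref: str, scoring: ScoringScheme, band: int, local: bool
) -> AlignmentResult:
    if not read:
        raise ValueError("empty read")
    if band < 1:
        raise ValueError("band must be >= 1")
    if not ref:
        raise ValueError("empty reference segment")
    score, ops_arr, i0, j0, i1, j1, matches, nm = _affine_banded(
        _codes(read),
        _codes(ref),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
        int(band),
        local,
    )
    ops = _run_length(ops_arr)
    res = AlignmentResult(
        score=int(score),
        cigar=cigar_text(ops),
        ref_begin=int(j0),
        ref_end=int(j1),
        read_begin=int(i0),
        read_end=int(i1),
        matches=int(matches),
        nm=int(nm),
        ops=ops,
    )
    _trim_boundary(ops, res)
    return res


def banded_global_align(
    read: str, ref_segment: str, scoring: ScoringScheme = ScoringScheme(), band: int = 64
) -> AlignmentResult:
    """Needleman–Wunsch with affine gaps restricted to a band; with
    ``band >= len(read) + len(ref_segment)`` it equals the unbanded optimum."""
    return _align(read, ref_segment, scoring, band, local=False)


def banded_local_align(
    read_sub: str, ref_sub: str, scoring: ScoringScheme = ScoringScheme(), band: int = 64
) -> AlignmentResult:
    """Smith–Waterman local alignment within the pair's intervals."""
    return _align(read_sub, ref_sub, scoring, band, local=True)


def default_band(vote_distance: int, read_len: int, margin: int = 16) -> int:
    """Band width: the cluster's voting distance plus a small margin."""
    return max(1, vote_distance + 2 * ceil(0.01 * read_len) + margin)


# ---------------------------------------------------------------------------
# Long-read CIGAR concatenation
# ---------------------------------------------------------------------------

MAX_CONCAT_GAP = 50_000


def concat_pair_cigars(
    results: list[AlignmentResult],
    read_oriented: str,
    ref_seq: str,
    scoring: ScoringScheme = ScoringScheme(),
    band: int = 64,
) -> list[AlignmentResult]:
    """Merge the aligned subsequence pairs of one read (same reference and
    strand) into as few records as possible.

    Pairs whose reference gap is at most 50,000 bases are concatenated: when
    both the read and reference gap sequences are non-empty and small (each
    ``<= 2 * band``) the gap is bridged by a global alignment, otherwise it is
    emitted as pure insertion/deletion operations.  Pairs farther apart stay
    separate records (candidate supplementary alignments).  Overlapping read
    intervals keep only the higher-scoring pair.
    """
    if not results:
        return []
    results = sorted(results, key=lambda r: (r.read_begin, r.read_end))
    merged: list[AlignmentResult] = []
    cur = results[0]
    for nxt in results[1:]:
        read_gap = nxt.read_begin - cur.read_end
        ref_gap = nxt.ref_begin - cur.ref_end
        if read_gap < 0 or ref_gap < 0:  # overlap: keep the better pair
            if nxt.score > cur.score:
                cur = nxt
            continue
        if ref_gap <= MAX_CONCAT_GAP:
            bridge_ops: list[tuple[int, int]] = []
            bridge_score = 0
            bridge_matches = 0
            bridge_nm = 0
            if 0 < read_gap <= 2 * band and 0 < ref_gap <= 2 * band:
                sub = banded_global_align(
                    read_oriented[cur.read_end : nxt.read_begin],
                    ref_seq[cur.ref_end : nxt.ref_begin],
                    scoring,
                    band=read_gap + ref_gap + 1,
                )
                # re-add any boundary deletions the sub-alignment trimmed
                lead = sub.ref_begin
                trail = ref_gap - sub.ref_end
                if lead:
                    bridge_ops.append((OP_D, lead))
                bridge_ops.extend(sub.ops)
                if trail:
                    bridge_ops.append((OP_D, trail))
                bridge_score = sub.score
                bridge_matches = sub.matches
                bridge_nm = sub.nm + lead + trail
            else:
                if read_gap:
                    bridge_ops.append((OP_I, read_gap))
                    bridge_score -= scoring.gap_open + scoring.gap_extend * read_gap
                    bridge_nm += read_gap
                if ref_gap:
                    bridge_ops.append((OP_D, ref_gap))
                    bridge_score -= scoring.gap_open + scoring.gap_extend * ref_gap
                    bridge_nm += ref_gap
            ops = list(cur.ops)
            for op, n in bridge_ops + nxt.ops:
                if ops and ops[-1][0] == op:
                    ops[-1] = (op, ops[-1][1] + n)
                else:
                    ops.append((op, n))
            cur = AlignmentResult(
                score=cur.score + bridge_score + nxt.score,
                cigar=cigar_text(ops),
                ref_begin=cur.ref_begin,
                ref_end=nxt.ref_end,
                read_begin=cur.read_begin,
                read_end=nxt.read_end,
                matches=cur.matches + bridge_matches + nxt.matches,
                nm=cur.nm + bridge_nm + nxt.nm,
                votes=cur.votes + nxt.votes,
                ops=ops,
            )
        else:
            merged.append(cur)
            cur = nxt
    merged.append(cur)
    return merged


# ---------------------------------------------------------------------------
# Classification, MAPQ, output
# ---------------------------------------------------------------------------


def classify_alignments(results: Sequence[AlignmentResult]) -> list[str]:
    """Categories parallel to *results*: the highest-scoring result is
    primary; another result is supplementary when its aligned pair length is
    shorter than 80% of the primary's, otherwise secondary."""
    if not results:
        return []
    order = sorted(range(len(results)), key=lambda i: -results[i].score)
    primary = order[0]
    plen = results[primary].read_end - results[primary].read_begin
    cats = ["secondary"] * len(results)
    cats[primary] = "primary"
    for i in order[1:]:
        rlen = results[i].read_end - results[i].read_begin
        cats[i] = "supplementary" if rlen < 0.8 * plen else "secondary"
    return cats


def compute_mapq(
    best_score: int,
    second_score: int,
    best_votes: int,
    best_identity: float,
) -> int:
    """Deterministic MAPQ surrogate in [0, 60].

    ``40 * (1 - second/best) * min(1, votes/10) + 20 * identity``, clamped.
    A unique perfect hit with >= 10 votes scores 60; two equal-score
    candidates cannot exceed 20.
    """
    if best_score <= 0:
        return 0
    ratio = max(0.0, min(1.0, second_score / best_score)) if second_score > 0 else 0.0
    q = 40.0 * (1.0 - ratio) * min(1.0, best_votes / 10.0) + 20.0 * best_identity
    return int(max(0, min(60, round(q))))


def sam_flag(category: str, strand: int) -> int:
    flag = 0
    if category == "unmapped":
        return 4
    if strand == 1:
        flag |= 16
    if category == "secondary":
        flag |= 256
    elif category == "supplementary":
        flag |= 2048
    return flag


def write_sam(
    records: Iterable[MappingRecord],
    names: Sequence[str],
    lengths: Sequence[int],
    out: TextIO,
    program_line: str = "dietmap",
) -> None:
    """Emit a SAM stream (@HD/@SQ/@PG header then one line per record)."""
    out.write("@HD\tVN:1.6\tSO:unsorted\n")
    for name, length in zip(names, lengths):
        out.write(f"@SQ\tSN:{name}\tLN:{int(length)}\n")
    out.write(f"@PG\tID:dietmap\tPN:dietmap\tCL:{program_line}\n")
    out.write("@CO\tMAPQ is a deterministic surrogate (score gap x votes + identity)\n")
    known = set(names)
    for r in records:
        if r.category != "unmapped" and r.ref_name not in known:
            raise ValueError(f"unknown reference {r.ref_name!r}")
        rname = "*" if r.category == "unmapped" else r.ref_name
        pos = 0 if r.category == "unmapped" else r.pos
        cig = "*" if r.category == "unmapped" else r.cigar
        tags = "" if r.category == "unmapped" else f"\tNM:i:{r.nm}\tAS:i:{r.score}"
        out.write(
            f"{r.read_name}\t{r.flag}\t{rname}\t{pos}\t{r.mapq}\t{cig}\t*\t0\t0\t"
            f"{r.seq}\t*{tags}\n"
        )


def write_paf(
    records: Iterable[MappingRecord],
    names: Sequence[str],
    lengths: Sequence[int],
    read_lengths: dict[str, int],
    out: TextIO,
) -> None:
    """PAF emission: 0-based half-open intervals, one line per mapped record."""
    lens = {n: int(l) for n, l in zip(names, lengths)}
    for r in records:
        if r.category == "unmapped":
            continue
        qlen = read_lengths.get(r.read_name, len(r.seq) if r.seq != "*" else 0)
        ref_len = lens[r.ref_name]
        ref_start = r.pos - 1
        consumed_ref = 0
        consumed_read = 0
        lead_clip = 0
        num = ""
        for ch in r.cigar:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch in "MX=":
                consumed_ref += n
                consumed_read += n
            elif ch == "D":
                consumed_ref += n
            elif ch == "I":
                consumed_read += n
            elif ch == "S" and consumed_read == 0 and consumed_ref == 0:
                lead_clip = n
        strand = "-" if r.strand else "+"
        q_start = lead_clip
        q_end = lead_clip + consumed_read
        out.write(
            f"{r.read_name}\t{qlen}\t{q_start}\t{q_end}\t{strand}\t{r.ref_name}\t"
            f"{ref_len}\t{ref_start}\t{ref_start + consumed_ref}\t{r.votes}\t"
            f"{consumed_ref}\t{r.mapq}\n"
        )
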