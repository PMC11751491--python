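"""2-bit DNA encoding, k-mer hashing, and (w, k)-minimizer extraction.

Seeds are *double-strand* minimizers: each k-mer is hashed on its canonical
strand (the lexicographically smaller of the packed forward and
reverse-complement encodings), and within every window of ``w`` consecutive
k-mers the k-mer(s) of minimal hash are emitted.  K-mers equal to their own
reverse complement are skipped, so no seed is strand-ambiguous.  Any window
touching an ambiguous base (N) emits nothing; scanning resumes after the N.

All extraction here is windowed over the *patterned* bases, but every emitted
position is the original (unpatterned) coordinate of the seed's first
included base, read from :attr:`PatternedSequence.origin_positions`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pattern import PatternedSequence

__all__ = [
    "EncodedSequence",
    "Minimizer",
    "MinimizerSet",
    "encode_sequence",
    "decode_sequence",
    "hash_kmer",
    "extract_minimizers",
    "extract_all_seeds",
    "extract_spaced_seeds",
]

MAX_K = 28  # 2-bit packing in a 64-bit word, upper bits reserved for bookkeeping

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
_CODE[ord("N")] = 254
_CODE[ord("n")] = 254

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

# large sentinel: no masked hash (<= 2^56) can reach it
_INVALID = np.int64(1) << 62


@dataclass
class EncodedSequence:
    """A DNA sequence packed to 2-bit codes (A=0, C=1, G=2, T=3).

    Positions holding N are recorded in ``ambiguous_mask``; their code slot is
    arbitrary and never read.
    """

    codes: np.ndarray  # uint8
    ambiguous_mask: np.ndarray  # bool
    name: str

    @property
    def length(self) -> int:
        return len(self.codes)

    @property
    def ambiguous(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.ambiguous_mask).tolist())

    def __len__(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class Minimizer:
    hash: int
    position: int  # original coordinate of the seed's first included base
    strand: str  # "forward" | "reverse"
    k: int
    w: int
    span: int  # original bases covered by the patterned k-mer


@dataclass
class MinimizerSet:
    """Column-oriented minimizer list (fast path for whole-genome sketching)."""

    hashes: np.ndarray  # uint64
    positions: np.ndarray  # int64, original coordinates
    strands: np.ndarray  # uint8: 0 forward, 1 reverse
    spans: np.ndarray  # int64
    k: int
    w: int

    def __len__(self) -> int:
        return len(self.hashes)

    def to_list(self) -> list[Minimizer]:
        return [
            Minimizer(
                hash=int(h),
                position=int(p),
                strand="forward" if s == 0 else "reverse",
                k=self.k,
                w=self.w,
                span=int(sp),
            )
            for h, p, s, sp in zip(self.hashes, self.positions, self.strands, self.spans)
        ]


def encode_sequence(seq: str, name: str = "") -> EncodedSequence:
    """Encode *seq* (over ``{A,C,G,T,N}``, case-insensitive) to 2-bit codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    bad = codes == 255
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValueError(f"invalid base {seq[pos]!r} at position {pos}")
    ambiguous = codes == 254
    codes = np.where(ambiguous, 0, codes).astype(np.uint8)
    return EncodedSequence(codes=codes, ambiguous_mask=ambiguous, name=name)


def decode_sequence(enc: EncodedSequence) -> str:
    out = _DECODE[enc.codes].copy()
    out[enc.ambiguous_mask] = ord("N")
    return out.tobytes().decode("ascii")


def _wang_mix(key: np.ndarray, mask: np.uint64) -> np.ndarray:
    """Thomas Wang's 64-bit invertible integer finalizer, masked to 2k bits."""
    key = (~key + (key << np.uint64(21))) & mask
    key = key ^ (key >> np.uint64(24))
    key = (key + (key << np.uint64(3)) + (key << np.uint64(8))) & mask
    key = key ^ (key >> np.uint64(14))
    key = (key + (key << np.uint64(2)) + (key << np.uint64(4))) & mask
    key = key ^ (key >> np.uint64(28))
    key = (key + (key << np.uint64(31))) & mask
    return key


def hash_kmer(packed: int, k: int) -> int:
    """Hash a 2-bit-packed k-mer; bijective on ``[0, 4**k)``."""
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}]")
    if not 0 <= packed < 4**k:
        raise ValueError("packed k-mer out of range")
    mask = np.uint64((1 << (2 * k)) - 1)
    return int(_wang_mix(np.array([packed], dtype=np.uint64), mask)[0])


def _pack_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed forward and reverse-complement encodings of every k-mer."""
    n = len(codes)
    nk = n - k + 1
    c = codes.astype(np.uint64)
    rc = (np.uint64(3) - c)
    fwd = np.zeros(nk, dtype=np.uint64)
    rev = np.zeros(nk, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | c[j : j + nk]
    for j in range(k - 1, -1, -1):
        rev = (rev << np.uint64(2)) | rc[j : j + nk]
    return fwd, rev


def _kmer_keys(
    codes: np.ndarray, ambiguous: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical masked hash (int64; ``_INVALID`` where unusable) and strand.

    A k-mer is unusable if it overlaps an N or equals its own reverse
    complement (palindrome).
    """
    nk = len(codes) - k + 1
    fwd, rev = _pack_kmers(codes, k)
    amb_cs = np.concatenate(([0], np.cumsum(ambiguous, dtype=np.int64)))
    has_n = (amb_cs[k:] - amb_cs[:-k]) > 0
    palindrome = fwd == rev
    strand = (rev < fwd).astype(np.uint8)
    canonical = np.minimum(fwd, rev)
    mask = np.uint64((1 << (2 * k)) - 1)
    hashes = _wang_mix(canonical, mask).astype(np.int64)
    hashes[has_n | palindrome] = _INVALID
    return hashes[:nk], strand[:nk]


def _minimizer_indices(keys: np.ndarray, w: int) -> np.ndarray:
    """Indices of k-mers that are the minimum of at least one valid window.

    A window is valid only when all of its ``w`` k-mer keys are valid.  Ties
    within a window keep every tied k-mer (preserves the both-ends guarantee
    of the minimizer scheme).
    """
    nk = len(keys)
    nwin = nk - w + 1
    if nwin < 1:
        return np.empty(0, dtype=np.int64)
    sw = np.lib.stride_tricks.sliding_window_view(keys, w)
    wmin = sw.min(axis=1)
    win_valid = sw.max(axis=1) < _INVALID
    wkey = np.where(win_valid, wmin, np.int64(-1))
    # for k-mer i, the covering windows start in [i-w+1, i]
    sentinel = np.full(w - 1, -1, dtype=np.int64)
    pad = np.concatenate((sentinel, wkey, sentinel))
    cover = np.lib.stride_tricks.sliding_window_view(pad, w).max(axis=1)
    hit = (keys < _INVALID) & (cover >= 0) & (keys == cover)
    return np.flatnonzero(hit)


def extract_minimizers(
    ps: PatternedSequence | EncodedSequence, k: int, w: int
) -> MinimizerSet:
    """Double-strand (w, k)-minimizers of a patterned (or plain) sequence.

    Accepts a :class:`PatternedSequence` (positions reported in original
    source coordinates) or an :class:`EncodedSequence` (identity coordinates).
    Returns an empty set when fewer than ``w`` k-mers exist.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}]")
    if w < 1:
        raise ValueError("w must be >= 1")
    if isinstance(ps, PatternedSequence):
        enc = encode_sequence(ps.bases)
        origin = ps.origin_positions
    else:
        enc = ps
        origin = np.arange(len(enc.codes), dtype=np.int64)
    empty = MinimizerSet(
        hashes=np.empty(0, dtype=np.uint64),
        positions=np.empty(0, dtype=np.int64),
        strands=np.empty(0, dtype=np.uint8),
        spans=np.empty(0, dtype=np.int64),
        k=k,
        w=w,
    )
    if len(enc.codes) < k:
        return empty
    keys, strand = _kmer_keys(enc.codes, enc.ambiguous_mask, k)
    idx = _minimizer_indices(keys, w)
    if len(idx) == 0:
        return empty
    return MinimizerSet(
        hashes=keys[idx].astype(np.uint64),
        positions=origin[idx],
        strands=strand[idx],
        spans=origin[idx + k - 1] - origin[idx] + 1,
        k=k,
        w=w,
    )


def extract_all_seeds(seq: str, k: int) -> list[int]:
    """Canonical hash of every overlapping k-mer (benchmark extractor).

    N bases split the sequence into runs; palindromic k-mers are kept (they
    are not strand-ambiguous for plain hashing purposes).
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}]")
    enc = encode_sequence(seq)
    if len(enc.codes) < k:
        return []
    fwd, rev = _pack_kmers(enc.codes, k)
    amb_cs = np.concatenate(([0], np.cumsum(enc.ambiguous_mask, dtype=np.int64)))
    has_n = (amb_cs[k:] - amb_cs[:-k]) > 0
    canonical = np.minimum(fwd, rev)
    mask = np.uint64((1 << (2 * k)) - 1)
    hashes = _wang_mix(canonical, mask)
    return hashes[~has_n].tolist()


def extract_spaced_seeds(seq: str, mask: str) -> list[int]:
    """Spaced seeds: the sequence stays unchanged and the binary *mask* is
    applied to each extracted seed, sampling the bases at its 1-positions.

    Every start position yields one seed (runs permitting), so the number of
    extracted seeds is independent of the mask's weight.
    """
    span = len(mask)
    offsets = [i for i, c in enumerate(mask) if c == "1"]
    if set(mask) - {"0", "1"} or not offsets:
        raise ValueError("mask must be binary with at least one 1")
    weight = len(offsets)
    if weight > MAX_K:
        raise ValueError(f"mask weight must be <= {MAX_K}")
    enc = encode_sequence(seq)
    n = len(enc.codes)
    ns = n - span + 1
    if ns < 1:
        return []
    c = enc.codes.astype(np.uint64)
    rc = np.uint64(3) - c
    fwd = np.zeros(ns, dtype=np.uint64)
    rev = np.zeros(ns, dtype=np.uint64)
    has_n = np.zeros(ns, dtype=bool)
    for j in offsets:
        fwd = (fwd << np.uint64(2)) | c[j : j + ns]
        has_n |= enc.ambiguous_mask[j : j + ns]
    for j in reversed(offsets):
        rev = (rev << np.uint64(2)) | rc[j : j + ns]
    canonical = np.minimum(fwd, rev)
    bits = np.uint64((1 << (2 * weight)) - 1)
    hashes = _wang_mix(canonical, bits)
    return hashes[~has_n].tolist()
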