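"""Independent oracles used by the test suite.

Everything here is deliberately written against the definitions, not against
the package implementation: brute-force window scans, quadratic clustering,
full-matrix DP, recursive memoized edit distance, and a standalone integer
implementation of the Wang finalizer.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numba import njit

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def wang_mix_int(key: int, bits: int) -> int:
    """Standalone integer implementation of Thomas Wang's 64-bit finalizer,
    masked to *bits* bits."""
    mask = (1 << bits) - 1
    key = (~key + (key << 21)) & mask
    key = key ^ (key >> 24)
    key = (key + (key << 3) + (key << 8)) & mask
    key = key ^ (key >> 14)
    key = (key + (key << 2) + (key << 4)) & mask
    key = key ^ (key >> 28)
    key = (key + (key << 31)) & mask
    return key


def brute_minimizers(bases: str, origin: list[int], k: int, w: int):
    """O(n*w) window-minimum oracle over the patterned bases.

    Returns the set of (hash, original_position, strand) triples: for every
    window of w consecutive k-mers, all k-mers of minimal canonical hash;
    windows touching an N emit nothing; palindromic k-mers are unusable.
    """
    n = len(bases)
    keys = []  # (hash, strand) or None per k-mer start
    for i in range(n - k + 1):
        kmer = bases[i : i + k]
        if "N" in kmer:
            keys.append(None)
            continue
        fwd = 0
        for c in kmer:
            fwd = fwd * 4 + _ENC[c]
        rev = 0
        for c in revcomp(kmer):
            rev = rev * 4 + _ENC[c]
        if fwd == rev:
            keys.append(None)
            continue
        strand = 0 if fwd < rev else 1
        keys.append((wang_mix_int(min(fwd, rev), 2 * k), strand))
    out = set()
    nk = len(keys)
    for t in range(nk - w + 1):
        window = keys[t : t + w]
        if any(x is None for x in window):
            continue
        m = min(h for h, _ in window)
        for off, item in enumerate(window):
            if item[0] == m:
                out.add((item[0], origin[t + off], item[1]))
    return out


def cluster_oracle(deltas_sorted: list[int], D: int):
    """Quadratic re-scan clustering oracle: repeatedly take the first
    unassigned delta as anchor and absorb every delta within D of it (they
    are sorted, so this matches the greedy left-to-right contract).
    Returns [(anchor, last, votes), ...]."""
    out = []
    i = 0
    n = len(deltas_sorted)
    while i < n:
        anchor = deltas_sorted[i]
        members = [d for d in deltas_sorted[i:] if d - anchor <= D]
        out.append((anchor, members[-1], len(members)))
        i += len(members)
    return out


@njit(cache=True)
def full_affine_score(a, b, match, mis, go, ge, local):  # pragma: no cover
    """Unbanded full-matrix affine-gap DP; returns the optimal score
    (global: bottom-right cell; local: best cell)."""
    m = a.shape[0]
    n = b.shape[0]
    NEG = -(1 << 40)
    H = np.full((m + 1, n + 1), NEG, np.int64)
    E = np.full((m + 1, n + 1), NEG, np.int64)
    F = np.full((m + 1, n + 1), NEG, np.int64)
    H[0, 0] = 0
    for j in range(1, n + 1):
        E[0, j] = -(go + ge * j)
        H[0, j] = 0 if local else E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = -(go + ge * i)
        H[i, 0] = 0 if local else F[i, 0]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e1 = H[i, j - 1] - go - ge
            e2 = E[i, j - 1] - ge
            E[i, j] = e1 if e1 > e2 else e2
            f1 = H[i - 1, j] - go - ge
            f2 = F[i - 1, j] - ge
            F[i, j] = f1 if f1 > f2 else f2
            s = match if a[i - 1] == b[j - 1] else -mis
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if local and h < 0:
                h = 0
            H[i, j] = h
            if local and h > best:
                best = h
    if local:
        return best
    return H[m, n]


def codes(seq: str) -> np.ndarray:
    return np.array([_ENC[c] for c in seq], dtype=np.int8)


def lev_oracle(a: str, b: str) -> int:
    """Recursive memoized unit-cost edit distance (small inputs only)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        return min(rec(i - 1, j) + 1, rec(i, j - 1) + 1, rec(i - 1, j - 1) + cost)

    return rec(len(a), len(b))


def cigar_score(cigar: str, read: str, ref: str, read_off: int, ref_off: int,
                match: int, mis: int, go: int, ge: int) -> int:
    """Recompute an alignment score by walking the CIGAR over the sequences."""
    i, j = read_off, ref_off
    score = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "M":
            for _ in range(n):
                score += match if read[i] == ref[j] else -mis
                i += 1
                j += 1
        elif ch == "I":
            score -= go + ge * n
            i += n
        elif ch == "D":
            score -= go + ge * n
            j += n
        elif ch == "S":
            i += n
    return score
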