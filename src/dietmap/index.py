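"""Compressed seed index: minimizers of the patterned reference, stored in
original (unpatterned) coordinates.

The reference is sparsified with the diet pattern at shift 0, minimizers are
extracted from the patterned copy, and every (hash, location) record is
appended to one flat array which is sorted once and grouped into the hash
table — the location stored is always the coordinate in the original
reference, so no patterned-to-original translation is ever needed at query
time.  Hashes occurring more than ``max_occ`` times are masked out at query
time (frequency filtering).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .pattern import DietPattern, apply_pattern
from .sketch import MAX_K, extract_minimizers

__all__ = ["SeedIndex", "IndexStats", "build_index", "query_index", "seed_occurrence", "index_stats"]

_FORMAT_MAGIC = "dietmap-index"
_FORMAT_VERSION = 1

_EMPTY = (
    np.empty(0, dtype=np.int32),
    np.empty(0, dtype=np.int64),
    np.empty(0, dtype=np.uint8),
    np.empty(0, dtype=np.int64),
)


@dataclass
class IndexStats:
    distinct_hashes: int
    total_locations: int
    density: float  # locations per original reference base


@dataclass
class SeedIndex:
    """Map from minimizer hash to its sorted list of reference locations."""

    pattern: DietPattern
    k: int
    w: int
    max_occ: int
    names: list[str]
    lengths: np.ndarray  # int64 per reference
    # location columns, sorted by (hash, ref_id, position)
    hashes: np.ndarray  # uint64 (one entry per location)
    ref_ids: np.ndarray  # int32
    positions: np.ndarray  # int64
    strands: np.ndarray  # uint8
    spans: np.ndarray  # int64
    # grouping: uniq[i] occupies rows [starts[i], starts[i+1])
    uniq: np.ndarray = field(repr=False, default=None)
    starts: np.ndarray = field(repr=False, default=None)
    sequences: list[str] | None = None  # original references (None if dropped)
    _lookup: dict = field(repr=False, default=None)

    def __post_init__(self):
        if self.uniq is None:
            self.uniq, self.starts = _group(self.hashes)
        if self._lookup is None:
            self._lookup = {int(h): i for i, h in enumerate(self.uniq)}

    # -- queries -----------------------------------------------------------
    def occurrence(self, h: int) -> int:
        """Occurrence count of hash *h*, or 0 if absent or hyper-frequent."""
        i = self._lookup.get(int(h))
        if i is None:
            return 0
        n = int(self.starts[i + 1] - self.starts[i])
        return n if n <= self.max_occ else 0

    def query(self, h: int):
        """Location columns (ref_ids, positions, strands, spans) for *h*,
        sorted by (ref_id, position); empty when absent or above max_occ."""
        i = self._lookup.get(int(h))
        if i is None:
            return _EMPTY
        lo, hi = int(self.starts[i]), int(self.starts[i + 1])
        if hi - lo > self.max_occ:
            return _EMPTY
        sl = slice(lo, hi)
        return self.ref_ids[sl], self.positions[sl], self.strands[sl], self.spans[sl]

    def stats(self) -> IndexStats:
        total_len = int(self.lengths.sum())
        return IndexStats(
            distinct_hashes=len(self.uniq),
            total_locations=len(self.hashes),
            density=(len(self.hashes) / total_len) if total_len else 0.0,
        )

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        params = {
            "magic": _FORMAT_MAGIC,
            "version": _FORMAT_VERSION,
            "pattern": self.pattern.text,
            "k": self.k,
            "w": self.w,
            "max_occ": self.max_occ,
            "names": self.names,
            "has_sequences": self.sequences is not None,
        }
        arrays = {
            "lengths": self.lengths,
            "hashes": self.hashes,
            "ref_ids": self.ref_ids,
            "positions": self.positions,
            "strands": self.strands,
            "spans": self.spans,
        }
        if self.sequences is not None:
            seq_blob = ("\n".join(self.sequences)).encode("ascii")
            arrays["seq_blob"] = np.frombuffer(seq_blob, dtype=np.uint8)
        arrays["params_json"] = np.frombuffer(
            json.dumps(params).encode("utf-8"), dtype=np.uint8
        )
        with open(path, "wb") as fh:
            np.savez_compressed(fh, **arrays)

    @classmethod
    def load(cls, path) -> "SeedIndex":
        from .pattern import parse_pattern

        with np.load(path) as z:
            params = json.loads(bytes(z["params_json"]).decode("utf-8"))
            if params.get("magic") != _FORMAT_MAGIC:
                raise ValueError(f"{path}: not a dietmap index")
            if params.get("version") != _FORMAT_VERSION:
                raise ValueError(
                    f"{path}: unsupported index format version {params.get('version')}"
                )
            sequences = None
            if params["has_sequences"]:
                sequences = bytes(z["seq_blob"]).decode("ascii").split("\n")
            return cls(
                pattern=parse_pattern(params["pattern"]),
                k=params["k"],
                w=params["w"],
                max_occ=params["max_occ"],
                names=list(params["names"]),
                lengths=z["lengths"].copy(),
                hashes=z["hashes"].copy(),
                ref_ids=z["ref_ids"].copy(),
                positions=z["positions"].copy(),
                strands=z["strands"].copy(),
                spans=z["spans"].copy(),
                sequences=sequences,
            )


def _group(hashes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, first = np.unique(hashes, return_index=True)
    starts = np.concatenate((first, [len(hashes)])).astype(np.int64)
    return uniq, starts


def build_index(
    refs: Iterable[tuple[str, str]],
    pattern: DietPattern,
    k: int,
    w: int,
    max_occ: int = 500,
    batch_bases: int = 500_000_000,
    keep_sequences: bool = True,
) -> SeedIndex:
    """Build the seed index over *refs* (iterable of ``(name, sequence)``).

    References are processed in batches of at most *batch_bases* original
    bases; a single reference longer than the batch is split into chunks with
    a ``(k + w) * p`` overlap (aligned to the pattern period) so that every
    minimizer window of the unsplit sequence is contained in some chunk, and
    boundary duplicates are removed afterwards.  With ``keep_sequences=False``
    the original sequences are dropped (smaller index; base-level alignment
    becomes unavailable).
    """
    refs = list(refs)
    if not refs:
        raise ValueError("empty reference set")
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K}")
    p = pattern.p
    min_batch = k * p
    if batch_bases < min_batch:
        raise ValueError(f"batch_bases must be >= k*p = {min_batch}")

    names: list[str] = []
    lengths: list[int] = []
    sequences: list[str] | None = [] if keep_sequences else None
    cols: list[tuple[np.ndarray, ...]] = []
    overlap = (k + w) * p

    batch: list[tuple[int, int, str]] = []  # (ref_id, chunk_start, chunk_seq)
    batch_load = 0

    def flush():
        nonlocal batch, batch_load
        for rid, start, chunk in batch:
            ps = apply_pattern(pattern, start % p, chunk)
            ms = extract_minimizers(ps, k, w)
            if len(ms):
                cols.append(
                    (
                        ms.hashes,
                        np.full(len(ms), rid, dtype=np.int32),
                        ms.positions + start,
                        ms.strands,
                        ms.spans,
                    )
                )
        batch = []
        batch_load = 0

    for rid, (name, seq) in enumerate(refs):
        seq = seq.upper()
        names.append(name)
        lengths.append(len(seq))
        if sequences is not None:
            sequences.append(seq)
        # split long references on pattern-period boundaries with overlap
        start = 0
        while start < len(seq):
            end = min(len(seq), start + batch_bases)
            batch.append((rid, start, seq[start:end]))
            batch_load += end - start
            if batch_load >= batch_bases:
                flush()
            if end == len(seq):
                break
            nxt = end - overlap
            start = max(start + p, (nxt // p) * p)  # period-aligned, always advancing
    flush()

    if cols:
        hashes = np.concatenate([c[0] for c in cols])
        ref_ids = np.concatenate([c[1] for c in cols])
        positions = np.concatenate([c[2] for c in cols])
        strands = np.concatenate([c[3] for c in cols])
        spans = np.concatenate([c[4] for c in cols])
        # sort by (hash, ref, position) and drop chunk-overlap duplicates
        order = np.lexsort((positions, ref_ids, hashes))
        hashes, ref_ids, positions, strands, spans = (
            hashes[order],
            ref_ids[order],
            positions[order],
            strands[order],
            spans[order],
        )
        keep = np.ones(len(hashes), dtype=bool)
        if len(hashes) > 1:
            dup = (
                (hashes[1:] == hashes[:-1])
                & (ref_ids[1:] == ref_ids[:-1])
                & (positions[1:] == positions[:-1])
            )
            keep[1:] = ~dup
        hashes, ref_ids, positions, strands, spans = (
            hashes[keep],
            ref_ids[keep],
            positions[keep],
            strands[keep],
            spans[keep],
        )
    else:
        hashes = np.empty(0, dtype=np.uint64)
        ref_ids = np.empty(0, dtype=np.int32)
        positions = np.empty(0, dtype=np.int64)
        strands = np.empty(0, dtype=np.uint8)
        spans = np.empty(0, dtype=np.int64)

    return SeedIndex(
        pattern=pattern,
        k=k,
        w=w,
        max_occ=max_occ,
        names=names,
        lengths=np.asarray(lengths, dtype=np.int64),
        hashes=hashes,
        ref_ids=ref_ids,
        positions=positions,
        strands=strands,
        spans=spans,
        sequences=sequences,
    )


def query_index(idx: SeedIndex, h: int) -> list[tuple[int, int, str]]:
    """Sorted ``(ref_id, position, strand)`` list for hash *h* (empty when
    absent or more frequent than ``max_occ``)."""
    refs, poss, strands, _ = idx.query(h)
    return [
        (int(r), int(pp), "forward" if s == 0 else "reverse")
        for r, pp, s in zip(refs, poss, strands)
    ]


def seed_occurrence(idx: SeedIndex, h: int) -> int:
    return idx.occurrence(h)


def index_stats(idx: SeedIndex) -> IndexStats:
    return idx.stats()
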