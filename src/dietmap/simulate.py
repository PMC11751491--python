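"""Synthetic genomes and reads with known truth locations.

Reads carry their truth in the name —
``<prefix><i>|ref=<name>|pos=<origin>|strand=<+/->|ed=<edits>`` — so mapping
accuracy can be scored without auxiliary files.  Substitutions are i.i.d.
per base; insertions and deletions occur at a per-base event rate with
geometric lengths (mean 2), the error geometry of a generic wgsim-style
simulator.  Everything is deterministic under the given seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .align import revcomp

__all__ = [
    "simulate_genome",
    "simulate_reads",
    "parse_truth",
    "truth_overlaps",
    "SimulatedReadSet",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRUTH_RE = re.compile(r"\|ref=(?P<ref>[^|]+)\|pos=(?P<pos>\d+)\|strand=(?P<strand>[+-])\|ed=(?P<ed>\d+)")


@dataclass
class SimulatedReadSet:
    reads: list[tuple[str, str]]
    sub_rate: float
    indel_rate: float
    seed: int

    def __iter__(self):
        return iter(self.reads)

    def __len__(self):
        return len(self.reads)


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0, name: str = "ref") -> tuple[str, str]:
    """Random genome with i.i.d. bases at the stated GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    gch = gc / 2.0
    codes = rng.choice(4, size=length, p=[at, gch, gch, at])
    return name, _BASES[codes].tobytes().decode("ascii")


def _mutate_window(window: str, sub_rate: float, indel_rate: float, rng) -> tuple[str, int]:
    """Apply per-base substitutions and geometric-length indels; returns the
    mutated sequence and the number of edit events applied."""
    arr = np.frombuffer(window.encode("ascii"), dtype=np.uint8).copy()
    codes = np.zeros(len(arr), dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        codes[arr == b] = i
    edits = 0
    if sub_rate > 0:
        mask = rng.random(len(arr)) < sub_rate
        n = int(mask.sum())
        if n:
            codes[mask] = (codes[mask] + rng.integers(1, 4, size=n)) % 4
            arr = _BASES[codes]
            edits += n
    seq = arr.tobytes().decode("ascii")
    if indel_rate > 0:
        n_events = rng.binomial(len(seq), indel_rate)
        if n_events:
            positions = np.sort(rng.integers(0, len(seq), size=n_events))[::-1]
            chars = "ACGT"
            s = seq
            for pos in positions.tolist():
                length = int(rng.geometric(0.5))
                if rng.random() < 0.5:  # insertion
                    ins = "".join(chars[rng.integers(0, 4)] for _ in range(length))
                    s = s[:pos] + ins + s[pos:]
                else:  # deletion
                    s = s[:pos] + s[pos + length :]
                edits += length
            seq = s
    return seq, edits


def simulate_reads(
    genomes: list[tuple[str, str]],
    n: int,
    length: int,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
    name_prefix: str = "sim",
) -> SimulatedReadSet:
    """Sample *n* reads of target *length*: uniform origins (genomes weighted
    by length), 50/50 strand, then the error process above.  Truth (origin
    reference, 0-based position, strand, edit count) is encoded in each read
    name."""
    if not 0.0 <= sub_rate < 1.0 or not 0.0 <= indel_rate < 1.0:
        raise ValueError("rates must be in [0, 1)")
    usable = [(name, seq) for name, seq in genomes if len(seq) >= length]
    if not usable:
        raise ValueError("read length exceeds every genome length")
    rng = np.random.default_rng(seed)
    weights = np.array([len(s) for _, s in usable], dtype=float)
    weights /= weights.sum()
    # reserve slack so deletions near the read end can still be filled
    slack = int(np.ceil(length * indel_rate * 6)) + 8 if indel_rate > 0 else 0
    reads: list[tuple[str, str]] = []
    for i in range(n):
        g = int(rng.choice(len(usable), p=weights))
        gname, gseq = usable[g]
        span = min(len(gseq), length + slack)
        origin = int(rng.integers(0, len(gseq) - span + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        window = gseq[origin : origin + span]
        if strand == "-":
            window = revcomp(window)
        if sub_rate > 0 or indel_rate > 0:
            mutated, edits = _mutate_window(window, sub_rate, indel_rate, rng)
        else:
            mutated, edits = window, 0
        read = mutated[:length]
        name = f"{name_prefix}{i}|ref={gname}|pos={origin}|strand={strand}|ed={edits}"
        reads.append((name, read))
    return SimulatedReadSet(reads=reads, sub_rate=sub_rate, indel_rate=indel_rate, seed=seed)


def parse_truth(read_name: str) -> dict:
    m = _TRUTH_RE.search(read_name)
    if not m:
        raise ValueError(f"no truth encoded in read name {read_name!r}")
    return {
        "ref": m.group("ref"),
        "pos": int(m.group("pos")),
        "strand": m.group("strand"),
        "edits": int(m.group("ed")),
    }


def truth_overlaps(record_ref: str, record_pos0: int, record_end0: int, read_name: str, read_len: int, slop: int = 0) -> bool:
    """Does a mapped interval overlap the read's true origin interval?"""
    truth = parse_truth(read_name)
    if record_ref != truth["ref"]:
        return False
    t_lo = truth["pos"] - slop
    t_hi = truth["pos"] + read_len + slop
    return record_pos0 < t_hi and record_end0 > t_lo
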