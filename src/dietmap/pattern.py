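"""Repeating binary "diet patterns" and their application to DNA sequences.

A diet pattern is a short binary string ``P`` of length ``p`` and weight ``x``
(number of 1s) that is conceptually repeated along a sequence: wherever the
repetition holds a 1 the base is kept, wherever it holds a 0 the base is
dropped.  The kept bases form the *patterned* (sparsified) sequence, which is
shorter than the original by the reduction ratio ``beta = p / x``.  The
original coordinates of the kept bases are retained so that every downstream
seed can be reported in unpatterned coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DietPattern",
    "PatternedSequence",
    "parse_pattern",
    "shift_pattern",
    "apply_pattern",
    "patterned_length",
]


@dataclass(frozen=True)
class DietPattern:
    """A repeating inclusion mask over {0, 1}.

    Attributes
    ----------
    bits
        Tuple of 0/1 ints; one period of the repeating mask.
    p
        Period length (``len(bits)``).
    x
        Weight: number of 1s in one period.
    beta
        Reduction ratio ``p / x``; e.g. pattern ``"10"`` halves a sequence.
    """

    bits: tuple[int, ...]

    @property
    def p(self) -> int:
        return len(self.bits)

    @property
    def x(self) -> int:
        return sum(self.bits)

    @property
    def beta(self) -> float:
        return self.p / self.x

    @property
    def text(self) -> str:
        return "".join(str(b) for b in self.bits)

    def __post_init__(self) -> None:
        if len(self.bits) < 1:
            raise ValueError("pattern must be non-empty")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("pattern bits must be 0 or 1")
        if sum(self.bits) == 0:
            raise ValueError("all-zero pattern would drop every base")


@dataclass
class PatternedSequence:
    """The kept bases of a sequence plus the map back to original coordinates.

    ``bases[i]`` equals base ``origin_positions[i]`` of the source sequence;
    ``origin_positions`` is strictly increasing.  The source itself is never
    modified.
    """

    bases: str
    origin_positions: np.ndarray  # int64, strictly increasing
    source_length: int
    shift: int
    name: str = field(default="")

    def __len__(self) -> int:
        return len(self.bases)


def parse_pattern(text: str) -> DietPattern:
    """Parse a pattern string such as ``"10"`` into a :class:`DietPattern`.

    Raises
    ------
    ValueError
        If *text* is empty, contains symbols outside ``{0,1}``, or is all
        zeros (no base would survive).
    """
    if not text:
        raise ValueError("pattern must be non-empty")
    if set(text) - {"0", "1"}:
        raise ValueError(f"invalid pattern symbol in {text!r}: only 0/1 allowed")
    return DietPattern(tuple(int(c) for c in text))


def shift_pattern(pattern: DietPattern, s: int) -> DietPattern:
    """Cyclic rotation of *pattern* starting its repetition ``s`` later.

    The infinite repetition of the result equals the infinite repetition of
    *pattern* read from index ``s``.
    """
    p = pattern.p
    if not 0 <= s < p:
        raise ValueError(f"shift {s} out of range [0, {p})")
    return DietPattern(pattern.bits[s:] + pattern.bits[:s])


def _mask_for(pattern: DietPattern, s: int, length: int) -> np.ndarray:
    """Boolean inclusion mask of *length* under shift ``s``.

    Position ``i`` is included iff ``bits[(i + s) mod p] == 1``.
    """
    p = pattern.p
    if not 0 <= s < p:
        raise ValueError(f"shift {s} out of range [0, {p})")
    bits = np.asarray(pattern.bits, dtype=bool)
    idx = (np.arange(length, dtype=np.int64) + s) % p
    return bits[idx]


def apply_pattern(
    pattern: DietPattern, s: int, seq: str, name: str = ""
) -> PatternedSequence:
    """Keep the bases of *seq* selected by *pattern* at shift ``s``.

    Lowercase (soft-masked) input is uppercased first; N bases are kept or
    dropped by the mask like any other base — ambiguity is handled by the
    sketcher downstream.
    """
    seq = seq.upper()
    mask = _mask_for(pattern, s, len(seq))
    positions = np.flatnonzero(mask).astype(np.int64)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    bases = arr[positions].tobytes().decode("ascii")
    return PatternedSequence(
        bases=bases,
        origin_positions=positions,
        source_length=len(seq),
        shift=s,
        name=name,
    )


def patterned_length(pattern: DietPattern, length: int, s: int) -> int:
    """Closed-form length of ``apply_pattern(pattern, s, seq).bases``.

    Counts whole periods exactly (``length * x / p`` when ``p | length``) plus
    the surviving positions of the final partial period.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    p, x = pattern.p, pattern.x
    full, rem = divmod(length, p)
    rotated = pattern.bits[s % p:] + pattern.bits[: s % p]
    return full * x + sum(rotated[:rem])
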