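"""Seeding-sensitivity benchmark: how well does each seeding algorithm
separate low-edit from high-edit sequence pairs?

For random sequence pairs (original vs substitution-mutated copy) the
benchmark computes the Levenshtein distance and the *seed matching rate* —
the fraction of the mutated copy's seeds that also occur in the original's
seed set — under four seeding algorithms: every overlapping k-mer
("all"), (w, k)-minimizers, spaced seeds (mask applied per seed, sequence
unchanged), and diet seeds (both sequences sparsified by the pattern at
shift 0, then minimizer-sketched).  A pair is *accepted* at an edit-distance
threshold when its rate reaches the minimum rate observed among pairs at or
below that threshold — a construction with zero false negatives by
definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .pattern import DietPattern, apply_pattern, parse_pattern
from .sketch import extract_all_seeds, extract_minimizers, extract_spaced_seeds

__all__ = [
    "ALGORITHMS",
    "SPACED_MASKS",
    "BenchmarkPair",
    "mutate_sequence",
    "levenshtein",
    "seed_matching_rate",
    "acceptance_threshold",
    "mask_from_pattern",
    "run_benchmark",
]

ALGORITHMS = ("all", "minimizer", "spaced", "diet")

# spaced-seed masks from the spaced-seeding literature, keyed by weight
SPACED_MASKS = {
    13: "1110110110111",
    18: "111001011001010111",
    21: "111101101101011101111",
}

_BASES = "ACGT"


@dataclass
class BenchmarkPair:
    original: str
    mutated: str
    edit_distance: int
    rates: dict[str, float]


def mutate_sequence(seq: str, n_subs: int, seed: int) -> str:
    """Substitute exactly *n_subs* positions (drawn without replacement) with
    a different base; deterministic under *seed*."""
    if not 0 <= n_subs <= len(seq):
        raise ValueError("n_subs out of range")
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for pos in positions.tolist():
        choices = [b for b in _BASES if b != out[pos]]
        out[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def levenshtein(a: str, b: str) -> int:
    """Unit-cost global edit distance."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def mask_from_pattern(pattern: DietPattern, k: int) -> str:
    """Spaced-seed mask obtained by repeating *pattern* until it holds ``k``
    ones, truncated at the last 1 (the per-seed view of the diet pattern)."""
    bits: list[str] = []
    ones = 0
    i = 0
    while ones < k:
        b = pattern.bits[i % pattern.p]
        bits.append(str(b))
        ones += b
        i += 1
    return "".join(bits)


def _seeds(seq: str, algorithm: str, k: int, w: int, mask: str | None, pattern: DietPattern | None) -> list[int]:
    if algorithm == "all":
        return extract_all_seeds(seq, k)
    if algorithm == "minimizer":
        from .sketch import encode_sequence

        return extract_minimizers(encode_sequence(seq), k, w).hashes.tolist()
    if algorithm == "spaced":
        if mask is None:
            raise ValueError("spaced seeding requires a mask")
        return extract_spaced_seeds(seq, mask)
    if algorithm == "diet":
        if pattern is None:
            raise ValueError("diet seeding requires a pattern")
        ps = apply_pattern(pattern, 0, seq)
        return extract_minimizers(ps, k, w).hashes.tolist()
    raise ValueError(f"unknown seeding algorithm {algorithm!r}")


def seed_matching_rate(
    a: str,
    b: str,
    algorithm: str,
    k: int = 8,
    w: int = 6,
    mask: str | None = None,
    pattern: DietPattern | str | None = None,
) -> float:
    """Fraction of *b*'s seeds whose hash occurs among *a*'s seeds.

    For ``"diet"`` both sequences are sparsified at shift 0 before minimizer
    extraction (paired pattern phases).  Defined as 0 when *b* yields no
    seeds.
    """
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    a_set = set(_seeds(a, algorithm, k, w, mask, pattern))
    b_seeds = _seeds(b, algorithm, k, w, mask, pattern)
    if not b_seeds:
        return 0.0
    matched = sum(1 for s in b_seeds if s in a_set)
    return matched / len(b_seeds)


def acceptance_threshold(
    pairs: list[BenchmarkPair], algorithm: str, ed_threshold: int
) -> float:
    """Minimum seed matching rate among pairs with edit distance at most
    *ed_threshold* (the rate threshold that accepts all of them)."""
    rates = [p.rates[algorithm] for p in pairs if p.edit_distance <= ed_threshold]
    if not rates:
        raise ValueError(f"no pair with edit distance <= {ed_threshold}")
    return min(rates)


def run_benchmark(
    n_pairs: int,
    length: int = 1000,
    k: int = 8,
    w: int = 6,
    pattern: str = "10",
    mask: str | None = None,
    max_subs: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate *n_pairs* mutated sequence pairs (substitution counts uniform
    over ``[0, max_subs]``) and score all four seeding algorithms.

    Returns a tidy table with one row per pair: ``edit_distance`` plus a
    ``rate_<algorithm>`` column each.  Deterministic under *seed*.
    """
    pat = parse_pattern(pattern)
    if mask is None:
        mask = SPACED_MASKS.get(k) or mask_from_pattern(pat, k)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pairs):
        original = "".join(_BASES[c] for c in rng.integers(0, 4, size=length).tolist())
        n_subs = int(rng.integers(0, min(max_subs, length) + 1))
        mutated = mutate_sequence(original, n_subs, seed=int(rng.integers(0, 2**31 - 1)))
        row = {
            "pair": i,
            "n_subs": n_subs,
            "edit_distance": levenshtein(original, mutated),
        }
        for alg in ALGORITHMS:
            row[f"rate_{alg}"] = seed_matching_rate(
                original, mutated, alg, k=k, w=w, mask=mask, pattern=pat
            )
        rows.append(row)
    return pd.DataFrame(rows)


def accepted_counts(table: pd.DataFrame, ed_threshold: int) -> dict[str, int]:
    """Per algorithm: number of pairs whose rate reaches the acceptance
    threshold derived from *ed_threshold* (zero false negatives by
    construction)."""
    out = {}
    for alg in ALGORITHMS:
        qual = table[table["edit_distance"] <= ed_threshold]
        if qual.empty:
            raise ValueError(f"no pair with edit distance <= {ed_threshold}")
        thr = qual[f"rate_{alg}"].min()
        out[alg] = int((table[f"rate_{alg}"] >= thr).sum())
    return out
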