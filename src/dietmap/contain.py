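"""Alignment-free containment search and simple taxonomic profiling.

A read set is classified against a multi-reference seed index with sequence
alignment disabled: a read counts as *mapped* to a reference as soon as the
location-voting step gives it a winning cluster there (or, in recovery mode,
unconditionally to its best-voted rescue cluster).  References with enough
mapped reads and coverage are accepted, and relative abundances are the
accepted references' mapped-read proportions.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .index import SeedIndex
from .mapping import (
    PatternAlignConfig,
    _cluster,
    adjust_and_sort_hits,
    compressed_seed,
    pattern_align,
)

__all__ = [
    "ContainmentReport",
    "AbundanceProfile",
    "classify_read_set",
    "accept_targets",
    "relative_abundance",
    "profile_metrics",
    "write_report_tsv",
]

AbundanceProfile = dict[str, float]


@dataclass
class ContainmentReport:
    names: list[str]
    lengths: dict[str, int]
    read_counts: dict[str, int] = field(default_factory=dict)
    base_counts: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0
    mapped_reads: int = 0

    def coverage(self, name: str) -> float:
        """Mapped-base sum divided by reference length."""
        length = self.lengths[name]
        return self.base_counts.get(name, 0) / length if length else 0.0


def classify_read_set(
    reads: Iterable[tuple[str, str]],
    idx: SeedIndex,
    D: int = 500,
    V: int = 3,
    t: int = 10,
    recovery: bool = False,
) -> ContainmentReport:
    """Tally reads onto references by pattern alignment + voting only.

    A read maps to the reference of its top vote cluster iff that cluster
    has at least ``V`` votes — or unconditionally (any cluster) when
    *recovery* is on.  Ties on the top vote count resolve to the smallest
    reference id.
    """
    report = ContainmentReport(
        names=list(idx.names),
        lengths={n: int(l) for n, l in zip(idx.names, idx.lengths)},
    )
    pattern = idx.pattern
    cfg = PatternAlignConfig(t=t)
    n_reads = 0
    for _name, seq in reads:
        n_reads += 1
        seq = seq.upper()
        if len(seq) < idx.k:
            continue
        a = pattern_align(seq, pattern, idx, cfg)
        ms = compressed_seed(seq, pattern, a, idx.k, idx.w)
        if len(ms) == 0:
            continue
        fwd, rev = adjust_and_sort_hits(ms, idx, len(seq))
        clusters = _cluster(fwd, D, 0) + _cluster(rev, D, 1)
        if not clusters:
            continue
        top = min(clusters, key=lambda c: (-c.votes, c.ref_id, c.anchor))
        if top.votes >= V or recovery:
            rname = idx.names[top.ref_id]
            report.read_counts[rname] = report.read_counts.get(rname, 0) + 1
            report.base_counts[rname] = report.base_counts.get(rname, 0) + len(seq)
            report.mapped_reads += 1
    if n_reads == 0:
        raise ValueError("empty read set")
    report.total_reads = n_reads
    return report


def accept_targets(
    report: ContainmentReport, min_reads: int = 50, min_coverage: float = 0.05
) -> set[str]:
    """References with at least *min_reads* mapped reads AND coverage at
    least *min_coverage* (both thresholds overridable to production scale)."""
    return {
        name
        for name in report.names
        if report.read_counts.get(name, 0) >= min_reads
        and report.coverage(name) >= min_coverage
    }


def relative_abundance(report: ContainmentReport, accepted: set[str]) -> AbundanceProfile:
    """Mapped-read proportions over the accepted references (sums to 1)."""
    if not accepted:
        raise ValueError("no accepted references")
    total = sum(report.read_counts.get(n, 0) for n in accepted)
    if total == 0:
        raise ValueError("accepted references have no mapped reads")
    return {n: report.read_counts.get(n, 0) / total for n in sorted(accepted)}


def profile_metrics(predicted: AbundanceProfile, truth: AbundanceProfile) -> tuple[float, float]:
    """Presence/absence F1 and abundance L1 error.

    F1 is the harmonic mean of precision (true predicted taxa / all predicted
    taxa) and recall (true predicted taxa / all true taxa); L1 sums
    ``|truth - predicted|`` over the union of taxa, counting taxa absent from
    one profile as abundance 0.
    """
    pred_taxa = {t for t, a in predicted.items() if a > 0}
    true_taxa = {t for t, a in truth.items() if a > 0}
    tp = len(pred_taxa & true_taxa)
    precision = tp / len(pred_taxa) if pred_taxa else 0.0
    recall = tp / len(true_taxa) if true_taxa else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    taxa = pred_taxa | true_taxa
    l1 = sum(abs(truth.get(t, 0.0) - predicted.get(t, 0.0)) for t in taxa)
    return f1, l1


def write_report_tsv(
    report: ContainmentReport,
    accepted: set[str],
    abundance: AbundanceProfile | None,
    out: TextIO = sys.stdout,
) -> None:
    out.write("ref_id\treads\tcoverage\taccepted\tabundance\n")
    for name in report.names:
        ab = abundance.get(name, 0.0) if abundance else 0.0
        out.write(
            f"{name}\t{report.read_counts.get(name, 0)}\t"
            f"{report.coverage(name):.4f}\t{int(name in accepted)}\t{ab:.6f}\n"
        )
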