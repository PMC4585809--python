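"""Assembly contiguity and gap statistics: Nx ladders, totals,
length-threshold counts, gap ratio, and scaffold → contig decomposition.

Nx is the length such that sequences at least that long contain ≥ x % of the
total assembly length; each Nx row also carries the cumulative sequence
count at that size. Contigs are obtained by splitting scaffolds at runs of
N; with the default run length of 1 (every N is a gap), contig bases plus
gap bases always reconstruct scaffold bases exactly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._util import round_half_up
from .sequence_io import SequenceRecord

DEFAULT_X_VALUES = (50, 60, 70, 80, 90)
DEFAULT_THRESHOLDS = (100, 2000)


@dataclass
class NxRow:
    x: int
    size: int
    count: int


@dataclass
class AssemblySummary:
    """Contiguity statistics for one sequence set (contigs or scaffolds)."""

    nx_rows: list[NxRow]
    longest: int
    total_size: int
    threshold_counts: dict[int, int]
    gap_bases: int
    gap_ratio: float
    n_sequences: int = 0

    def nx(self, x: int) -> NxRow:
        for row in self.nx_rows:
            if row.x == x:
                return row
        raise KeyError(f"N{x} not computed")

    def to_dict(self) -> dict:
        return {
            "n_sequences": self.n_sequences,
            "total_size": self.total_size,
            "longest": self.longest,
            "gap_bases": self.gap_bases,
            "gap_ratio": self.gap_ratio,
            "nx": {f"N{r.x}": {"size": r.size, "count": r.count} for r in self.nx_rows},
            "threshold_counts": {
                f">={t} bp": c for t, c in self.threshold_counts.items()
            },
        }


def scaffolds_to_contigs(
    records: Sequence[SequenceRecord], min_gap_run: int = 1
) -> list[SequenceRecord]:
    """Split scaffolds at every maximal run of ≥ ``min_gap_run`` Ns."""
    if min_gap_run < 1:
        raise ValueError("min_gap_run must be >= 1")
    splitter = re.compile("N{%d,}" % min_gap_run)
    contigs: list[SequenceRecord] = []
    for rec in records:
        for i, piece in enumerate(splitter.split(rec.seq)):
            if piece:
                contigs.append(SequenceRecord(f"{rec.id}_ctg{i}", piece))
    return contigs


def nx_ladder(lengths: Sequence[int], x_values: Sequence[int] = DEFAULT_X_VALUES
              ) -> list[NxRow]:
    """Nx sizes and cumulative counts for each x (percent of total).

    Lengths are sorted descending; Nx size is the length at which the
    cumulative sum first reaches x % of the total, and Nx count the number
    of sequences up to and including it.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("need at least one sequence length")
    if (lengths <= 0).any():
        raise ValueError("all lengths must be positive")
    for x in x_values:
        if not 0 < x < 100:
            raise ValueError(f"x value {x} outside (0, 100)")
    srt = np.sort(lengths)[::-1]
    cum = np.cumsum(srt)
    total = cum[-1]
    rows = []
    for x in x_values:
        idx = int(np.searchsorted(cum, x / 100.0 * total))
        rows.append(NxRow(x=x, size=int(srt[idx]), count=idx + 1))
    return rows


def gap_stats(records: Sequence[SequenceRecord]) -> tuple[int, float]:
    """(total N bases, N fraction of all bases) across the sequence set."""
    gap = sum(rec.seq.count("N") for rec in records)
    total = sum(rec.length for rec in records)
    if total == 0:
        warnings.warn("empty sequence set; gap ratio reported as 0")
        return 0, 0.0
    return gap, gap / total


def gap_ratio_from_totals(scaffold_total: int, contig_total: int) -> float:
    """Gap ratio from the two printed totals:
    (scaffold bases − contig bases) / scaffold bases."""
    if scaffold_total <= 0:
        raise ValueError("scaffold_total must be positive")
    if contig_total > scaffold_total:
        raise ValueError("contig total exceeds scaffold total")
    return (scaffold_total - contig_total) / scaffold_total


def summarize_sequences(
    records: Sequence[SequenceRecord],
    x_values: Sequence[int] = DEFAULT_X_VALUES,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    min_length: int = 0,
) -> AssemblySummary:
    """One-level summary (no contig decomposition) of a sequence set."""
    lengths = [r.length for r in records if r.length >= min_length]
    if not lengths:
        raise ValueError("no sequences to summarize")
    gap_bases, gap_ratio = gap_stats(records)
    return AssemblySummary(
        nx_rows=nx_ladder(lengths, x_values),
        longest=max(lengths),
        total_size=sum(lengths),
        threshold_counts={t: sum(1 for L in lengths if L >= t) for t in thresholds},
        gap_bases=gap_bases,
        gap_ratio=gap_ratio,
        n_sequences=len(lengths),
    )


@dataclass
class AssemblyReport:
    scaffolds: AssemblySummary
    contigs: AssemblySummary
    min_gap_run: int = 1

    def to_dict(self) -> dict:
        return {
            "min_gap_run": self.min_gap_run,
            "scaffolds": self.scaffolds.to_dict(),
            "contigs": self.contigs.to_dict(),
        }


def summarize_assembly(
    records: Sequence[SequenceRecord],
    x_values: Sequence[int] = DEFAULT_X_VALUES,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    min_gap_run: int = 1,
    min_length: int = 0,
) -> AssemblyReport:
    """Scaffold-level and contig-level summaries of one assembly."""
    scaff = summarize_sequences(records, x_values, thresholds, min_length)
    contigs = scaffolds_to_contigs(records, min_gap_run)
    ctg = summarize_sequences(contigs, x_values, thresholds, min_length)
    return AssemblyReport(scaffolds=scaff, contigs=ctg, min_gap_run=min_gap_run)


def report_tsv(report: AssemblyReport, path) -> None:
    """Write a two-column-pair table (contig / scaffold) of the ladder,
    longest, totals, threshold counts and gap ratio."""
    c, s = report.contigs, report.scaffolds
    with open(path, "w") as fh:
        fh.write("row\tcontig_size\tcontig_number\tscaffold_size\tscaffold_number\n")
        for rc, rs in zip(reversed(c.nx_rows), reversed(s.nx_rows)):
            fh.write(f"N{rc.x}\t{rc.size}\t{rc.count}\t{rs.size}\t{rs.count}\n")
        fh.write(f"Longest\t{c.longest}\t\t{s.longest}\t\n")
        fh.write(f"Total size\t{c.total_size}\t\t{s.total_size}\t\n")
        for t in c.threshold_counts:
            fh.write(
                f">={t} bp\t\t{c.threshold_counts[t]}\t\t{s.threshold_counts[t]}\n"
            )
        fh.write(
            f"Gap ratio (%)\t{round_half_up(100 * c.gap_ratio, 2)}\t\t"
            f"{round_half_up(100 * s.gap_ratio, 2)}\t\n"
        )
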