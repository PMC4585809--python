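"""Sequencing-effort accounting: read depth, physical coverage and
C-value (picogram → base pair) conversion.

Read depth is total sequenced bases over genome size; physical coverage is
the mean number of read-pair inserts spanning a base, n_pairs × insert /
genome size — for long-insert mate-pair libraries it greatly exceeds read
depth and is what matters for scaffolding power.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import round_half_up

#: Doležel convention: one picogram of DNA is 0.978×10^9 bp.
BP_PER_PG = 0.978e9


@dataclass
class LibraryAccounting:
    """Per-library sequencing metadata and derived pair count."""

    insert_size: int
    read_length: int
    total_bases: float
    n_pairs: int | None = None

    def __post_init__(self):
        if self.total_bases < 0:
            raise ValueError("total_bases must be non-negative")
        if self.n_pairs is None:
            if self.read_length <= 0:
                raise ValueError("read_length must be positive to derive n_pairs")
            self.n_pairs = int(round(self.total_bases / (2 * self.read_length)))


def pg_to_bp(mass_pg: float) -> float:
    """Convert a haploid DNA mass in picograms to base pairs."""
    if mass_pg < 0:
        raise ValueError("mass must be non-negative")
    return mass_pg * BP_PER_PG


def read_depth(total_bases: float, genome_size: float) -> float:
    """Fold read depth: total sequenced bases / genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return total_bases / genome_size


def physical_coverage(n_pairs: float, insert_size: float, genome_size: float) -> float:
    """Mean number of read-pair inserts spanning a base."""
    if n_pairs <= 0 or insert_size <= 0 or genome_size <= 0:
        raise ValueError("all arguments must be positive")
    return n_pairs * insert_size / genome_size


def percent_of(part: float, whole: float, decimals: int = 2) -> float:
    """100 × part / whole, rounded half-up to ``decimals``.

    The generic percentage arithmetic behind completeness and support
    ratios (e.g. 246 of 248 core genes → 99 %).
    """
    if whole <= 0:
        raise ValueError("whole must be positive")
    if part < 0:
        raise ValueError("part must be non-negative")
    return round_half_up(100.0 * part / whole, decimals)


def summarize_libraries(libraries: pd.DataFrame, genome_size: float) -> pd.DataFrame:
    """Add depth and physical-coverage columns to a library table.

    ``libraries`` needs columns insert_size, read_length, total_bases
    (optionally n_pairs). Returns a copy with average_read_depth and
    physical_coverage columns plus a Total row.
    """
    df = libraries.copy()
    if "n_pairs" not in df.columns:
        df["n_pairs"] = (df["total_bases"] / (2 * df["read_length"])).round().astype(
            "int64"
        )
    df["average_read_depth"] = df["total_bases"] / genome_size
    df["physical_coverage"] = df["n_pairs"] * df["insert_size"] / genome_size
    total = pd.DataFrame(
        {
            "insert_size": [pd.NA],
            "read_length": [pd.NA],
            "total_bases": [df["total_bases"].sum()],
            "n_pairs": [df["n_pairs"].sum()],
            "average_read_depth": [df["total_bases"].sum() / genome_size],
            "physical_coverage": [df["physical_coverage"].sum()],
        },
        index=["Total"],
    )
    return pd.concat([df, total])
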