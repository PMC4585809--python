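"""Sequence, interval and partition I/O plus the shared coordinate conventions.

All coordinates inside the toolkit are 0-based half-open; dialects that use
1-based inclusive coordinates (GFF3, RepeatMasker ``.out``) are converted at
the I/O boundary and converted back on write. Strand is ignored throughout:
every statistic downstream (GC, repeat fractions, lengths) is
strand-symmetric.

Soft-masking (lowercase residues) in FASTA input is preserved as a per-base
boolean mask on :class:`SequenceRecord` so that repeat-masked fractions remain
recoverable after the sequence itself is uppercased.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

PARTITION_CLASSES = ("macro", "micro", "Z", "unassigned")

_INTERVAL_DIALECTS = ("BED", "GFF3", "repeatmasker_out")


class FormatError(ValueError):
    """Malformed input file; message names the offending line."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


@dataclass
class SequenceRecord:
    """One named DNA sequence over {A,C,G,T,N} plus tolerated IUPAC codes.

    ``mask`` flags soft-masked (lowercase-in-input) positions; ``None`` means
    nothing was masked.
    """

    id: str
    seq: str
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.mask is not None and len(self.mask) != len(self.seq):
            raise ValueError(f"mask length != sequence length for {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def masked_fraction(self) -> float:
        if self.mask is None or not self.seq:
            return 0.0
        return float(self.mask.mean())


@dataclass(frozen=True)
class GenomicInterval:
    """A category-labelled genomic interval, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    category: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomePartition:
    """Scaffold → chromosome-class assignment (macro / micro / Z).

    Sequences absent from the mapping belong to class ``unassigned``.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for seq_id, cls in self.mapping.items():
            if cls not in PARTITION_CLASSES:
                raise ValueError(
                    f"unknown class {cls!r} for {seq_id!r}; "
                    f"allowed: {', '.join(PARTITION_CLASSES)}"
                )

    def classify(self, seq_id: str) -> str:
        return self.mapping.get(seq_id, "unassigned")

    def classes(self) -> set[str]:
        return set(self.mapping.values()) | {"unassigned"}


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) multi-record FASTA file.

    Residues are uppercased; lowercase input is recorded in the per-base
    soft-mask. Raises :class:`FormatError` naming the line for an empty file
    or sequence data appearing before the first header.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    chunks: list[str] = []

    def flush(line_no):
        if cur_id is None:
            return
        seq = "".join(chunks)
        mask = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) >= ord("a")
        records.append(
            SequenceRecord(cur_id, seq.upper(), mask.copy() if mask.any() else None)
        )

    with _open_text(path) as fh:
        n = 0
        for n, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush(n)
                cur_id = line[1:].split()[0] if line[1:].split() else ""
                if not cur_id:
                    raise FormatError(f"{path}: empty FASTA header at line {n}")
                if cur_id in seen:
                    raise FormatError(f"{path}: duplicate id {cur_id!r} at line {n}")
                seen.add(cur_id)
                chunks = []
            else:
                if cur_id is None:
                    raise FormatError(
                        f"{path}: sequence before first header at line {n}"
                    )
                chunks.append(line)
        if cur_id is None:
            raise FormatError(f"{path}: empty file (no FASTA records) at line {n or 0}")
        flush(n)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write FASTA at a fixed line width, restoring soft-mask lowercase."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.seq
            if rec.mask is not None and rec.mask.any():
                arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
                lower = arr + 32
                arr[rec.mask & (arr >= ord("A")) & (arr <= ord("Z"))] = lower[
                    rec.mask & (arr >= ord("A")) & (arr <= ord("Z"))
                ]
                seq = arr.tobytes().decode("ascii")
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq_sequences(path) -> Iterator[str]:
    """Yield read sequences from a (possibly gzipped) FASTQ file.

    Quality strings are passed over, not interpreted.
    """
    from Bio import SeqIO

    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


# ---------------------------------------------------------------------------
# Intervals

def read_intervals(path, dialect: str = "BED") -> list[GenomicInterval]:
    """Read intervals in BED4, GFF3 or RepeatMasker ``.out`` dialect.

    All coordinates are normalised to 0-based half-open (GFF3 and
    RepeatMasker are 1-based inclusive on input). The category is the BED
    name column, the GFF3 feature-type column, or the RepeatMasker
    class/family column truncated at the first ``/``.
    """
    if dialect not in _INTERVAL_DIALECTS:
        raise ValueError(f"dialect must be one of {_INTERVAL_DIALECTS}")
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        lines = fh.readlines()

    def err(n, msg):
        raise FormatError(f"{path}: {msg} at line {n}")

    if dialect == "repeatmasker_out":
        lines = lines[3:]  # two header lines + one blank
        for n, line in enumerate(lines, start=4):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 11:
                err(n, "truncated RepeatMasker row")
            seq_id, start, end = parts[4], int(parts[5]) - 1, int(parts[6])
            category = parts[10].split("/")[0]
            if end <= start:
                err(n, f"interval end <= start ({start}, {end})")
            out.append(GenomicInterval(seq_id, start, end, category))
        return out

    for n, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if dialect == "BED":
            if len(parts) < 3:
                err(n, "BED row with fewer than 3 columns")
            seq_id, start, end = parts[0], int(parts[1]), int(parts[2])
            category = parts[3] if len(parts) > 3 else ""
        else:  # GFF3
            if len(parts) < 5:
                err(n, "GFF3 row with fewer than 5 columns")
            seq_id, category = parts[0], parts[2]
            start, end = int(parts[3]) - 1, int(parts[4])
        if end <= start or start < 0:
            err(n, f"interval end <= start after conversion ({start}, {end})")
        out.append(GenomicInterval(seq_id, start, end, category))
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path,
                    dialect: str = "BED") -> None:
    """Write intervals as BED4 or minimal GFF3 (coordinates converted back)."""
    if dialect not in ("BED", "GFF3"):
        raise ValueError("writable dialects: BED, GFF3")
    with open(path, "w") as fh:
        if dialect == "GFF3":
            fh.write("##gff-version 3\n")
        for iv in intervals:
            if dialect == "BED":
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.category}\n")
            else:
                fh.write(
                    f"{iv.seq_id}\tglk\t{iv.category or 'region'}\t"
                    f"{iv.start + 1}\t{iv.end}\t.\t.\t.\t.\n"
                )


# ---------------------------------------------------------------------------
# Partition

def read_partition(path) -> GenomePartition:
    """Read a two-column (seq_id, class) TSV into a :class:`GenomePartition`."""
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: expected 2 columns at line {n}")
            seq_id, cls = parts
            if seq_id in mapping:
                raise FormatError(f"{path}: duplicate seq_id {seq_id!r} at line {n}")
            if cls not in PARTITION_CLASSES:
                raise FormatError(
                    f"{path}: unknown class {cls!r} at line {n}; "
                    f"allowed: {', '.join(PARTITION_CLASSES)}"
                )
            mapping[seq_id] = cls
    return GenomePartition(mapping)


def write_partition(partition: GenomePartition, path) -> None:
    with open(path, "w") as fh:
        for seq_id, cls in partition.mapping.items():
            fh.write(f"{seq_id}\t{cls}\n")
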