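"""Synthetic genomes, reads, assemblies and annotations with known truth.

Every generator is a pure function of its explicit seed and emits a
machine-readable truth record sufficient to verify the downstream statistic
without re-deriving it. The generators emulate the statistical structure the
analyses assume:

* a diploid genome with tunable per-base heterozygosity, whose error-free
  read set yields a bimodal k-mer spectrum with the heterozygous mode at
  half the homozygous copy number;
* genomes with block-isochore GC structure (defaults: 1 Mbp blocks at GC
  0.35 / 0.55) versus homogeneous i.i.d. GC (default p = 0.418, a realistic
  reptile genome-wide mean), giving the flat-vs-decaying SD-vs-scale
  contrast;
* gappy assemblies with known contig lengths, N-run gaps, N50 and gap
  ratio;
* repeat interval sets with known union sizes, gene models with known mean
  exon/intron statistics, and expression count tables with closed-form RPKM.

The read simulator is substitution-only (no indels) with uniform start
positions — sufficient for every statistic in scope, but it does not
emulate real base-quality profiles, GC-coverage bias or structural
variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence_io import GenomicInterval, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenomeSpec:
    """Parameters of one synthetic haploid/diploid genome.

    ``gc_model`` is ("uniform", p) or
    ("blocks", block_length_bp, gc_levels, proportions).
    """

    length: int
    gc_model: tuple = ("uniform", 0.418)
    heterozygosity: float = 0.0
    repeat_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be positive")
        if not 0 <= self.heterozygosity < 1:
            raise ValueError("heterozygosity must be in [0, 1)")
        if not 0 <= self.repeat_fraction < 1:
            raise ValueError("repeat_fraction must be in [0, 1)")
        if self.gc_model[0] == "blocks":
            _, _, levels, props = self.gc_model
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError("block proportions must sum to 1")
            if len(levels) != len(props):
                raise ValueError("one proportion per GC level")


@dataclass
class ReadSimSpec:
    """Parameters of one simulated read set."""

    coverage: float
    read_length: int
    paired: bool = False
    insert_size: int = 0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.paired and self.insert_size < self.read_length:
            raise ValueError("insert_size must be >= read_length for pairs")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """i.i.d. base array (uint8 ASCII) with P(G or C) = gc."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _gc_blocks(rng, length, block_length, levels, proportions) -> np.ndarray:
    out = np.empty(length, dtype=np.uint8)
    pos = 0
    while pos < length:
        gc = levels[rng.choice(len(levels), p=np.asarray(proportions))]
        n = min(block_length, length - pos)
        out[pos : pos + n] = _random_sequence(rng, n, gc)
        pos += n
    return out


def make_haploid_genome(spec: GenomeSpec) -> tuple[SequenceRecord, dict]:
    """One haplotype drawn from the GC model, plus a truth record."""
    rng = np.random.default_rng(spec.seed)
    kind = spec.gc_model[0]
    if kind == "uniform":
        arr = _random_sequence(rng, spec.length, spec.gc_model[1])
    elif kind == "blocks":
        _, block_length, levels, props = spec.gc_model
        arr = _gc_blocks(rng, spec.length, block_length, levels, props)
    else:
        raise ValueError(f"unknown gc model {kind!r}")
    truth: dict = {"length": spec.length, "gc_model": list(spec.gc_model), "seed": spec.seed}
    if spec.repeat_fraction > 0:
        unit_len = min(500, max(50, spec.length // 20))
        unit = _random_sequence(rng, unit_len, 0.5)
        n_copies = int(spec.repeat_fraction * spec.length / unit_len)
        starts = rng.integers(0, spec.length - unit_len, size=n_copies)
        for s in starts:
            arr[s : s + unit_len] = unit
        truth["repeat_intervals"] = [
            [int(s), int(s) + unit_len] for s in sorted(starts)
        ]
    gc_count = int(((arr == ord("G")) | (arr == ord("C"))).sum())
    truth["gc_fraction"] = gc_count / spec.length
    return SequenceRecord("synth_hap", arr.tobytes().decode("ascii")), truth


def make_diploid_genome(spec: GenomeSpec) -> tuple[SequenceRecord, SequenceRecord, dict]:
    """Two haplotypes: B is A with substitutions at the heterozygosity rate.

    The truth record stores the exact variant positions and the realized
    per-base heterozygosity.
    """
    hap_a, truth = make_haploid_genome(spec)
    rng = np.random.default_rng((spec.seed, 1))
    arr = np.frombuffer(hap_a.seq.encode("ascii"), dtype=np.uint8).copy()
    n_sites = rng.binomial(spec.length, spec.heterozygosity)
    sites = rng.choice(spec.length, size=n_sites, replace=False)
    # substitute with one of the three other bases
    for s in sites:
        cur = arr[s]
        choices = _BASES[_BASES != cur]
        arr[s] = choices[rng.integers(0, 3)]
    hap_b = SequenceRecord("synth_hap_b", arr.tobytes().decode("ascii"))
    truth = dict(truth)
    truth["variant_positions"] = sorted(int(s) for s in sites)
    truth["realized_heterozygosity"] = n_sites / spec.length
    return SequenceRecord("synth_hap_a", hap_a.seq), hap_b, truth


_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


def _revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


def simulate_reads(
    haplotypes: Sequence[SequenceRecord], spec: ReadSimSpec
) -> list[tuple[str, str]]:
    """Uniform-start substitution-error reads, coverage split equally
    across haplotypes. Returns (read_id, sequence) tuples; deterministic
    under the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    reads: list[tuple[str, str]] = []
    L = spec.read_length
    for h, hap in enumerate(haplotypes):
        arr = np.frombuffer(hap.seq.encode("ascii"), dtype=np.uint8)
        if L > arr.size:
            raise ValueError("read_length exceeds genome length")
        cov = spec.coverage / len(haplotypes)
        if spec.paired:
            span = spec.insert_size
            n_pairs = int(round(cov * arr.size / (2 * L)))
            starts = rng.integers(0, arr.size - span + 1, size=n_pairs)
            for i, s in enumerate(starts):
                fwd = arr[s : s + L].copy()
                rev = _revcomp(arr[s + span - L : s + span].copy())
                for j, mate in enumerate((fwd, rev), start=1):
                    _add_errors(rng, mate, spec.error_rate)
                    reads.append(
                        (f"h{h}_p{i}/{j}", mate.tobytes().decode("ascii"))
                    )
        else:
            n_reads = int(round(cov * arr.size / L))
            starts = rng.integers(0, arr.size - L + 1, size=n_reads)
            for i, s in enumerate(starts):
                read = arr[s : s + L].copy()
                if rng.random() < 0.5:
                    read = _revcomp(read)
                _add_errors(rng, read, spec.error_rate)
                reads.append((f"h{h}_r{i}", read.tobytes().decode("ascii")))
    return reads


def _add_errors(rng, read: np.ndarray, error_rate: float) -> None:
    if error_rate <= 0:
        return
    n_err = rng.binomial(read.size, error_rate)
    if n_err == 0:
        return
    pos = rng.choice(read.size, size=n_err, replace=False)
    for p in pos:
        choices = _BASES[_BASES != read[p]]
        read[p] = choices[rng.integers(0, 3)]


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    """Write simulated reads as FASTQ with uniform quality 'I'."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# assemblies

def make_assembly(
    n_scaffolds: int = 50,
    mean_contig_length: int = 2_000,
    contigs_per_scaffold: int = 4,
    gap_length: int = 100,
    gap_model: str = "fixed",
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict]:
    """Scaffolds built from known contigs joined by N runs, plus truth.

    ``gap_model`` "none" emits gap-free single-contig scaffolds. The truth
    record carries the exact contig lengths, gap bases, totals, gap ratio
    and the constructed N50s (computed by direct cumulative enumeration).
    """
    rng = np.random.default_rng(seed)
    scaffolds: list[SequenceRecord] = []
    contig_lengths: list[int] = []
    scaffold_lengths: list[int] = []
    gap_bases = 0
    for i in range(n_scaffolds):
        k = 1 if gap_model == "none" else contigs_per_scaffold
        lens = rng.geometric(1.0 / mean_contig_length, size=k)
        parts = []
        for j, L in enumerate(lens):
            if j > 0:
                g = gap_length if gap_model == "fixed" else int(rng.integers(1, 2 * gap_length))
                parts.append("N" * g)
                gap_bases += g
            parts.append(
                _random_sequence(rng, int(L), 0.42).tobytes().decode("ascii")
            )
            contig_lengths.append(int(L))
        seq = "".join(parts)
        scaffold_lengths.append(len(seq))
        scaffolds.append(SequenceRecord(f"scaffold_{i}", seq))

    def n50(lengths):
        srt = sorted(lengths, reverse=True)
        half, cum = sum(srt) / 2, 0
        for L in srt:
            cum += L
            if cum >= half:
                return L

    truth = {
        "seed": seed,
        "contig_lengths": contig_lengths,
        "scaffold_lengths": scaffold_lengths,
        "contig_total": sum(contig_lengths),
        "scaffold_total": sum(scaffold_lengths),
        "gap_bases": gap_bases,
        "gap_ratio": gap_bases / sum(scaffold_lengths),
        "contig_n50": n50(contig_lengths),
        "scaffold_n50": n50(scaffold_lengths),
    }
    return scaffolds, truth


# ---------------------------------------------------------------------------
# annotations

@dataclass
class CategorySpec:
    """Planted-repeat request: target genome fraction for one category,
    optionally emitted as several overlapping interval layers (methods)."""

    category: str
    fraction: float
    n_methods: int = 1
    interval_length: int = 500


def make_annotations(
    genome: SequenceRecord,
    category_specs: Sequence[CategorySpec],
    n_genes: int = 20,
    exons_per_gene: int = 3,
    exon_length: int = 150,
    intron_length: int = 300,
    n_samples: int = 3,
    seed: int = 0,
) -> dict:
    """Plant repeat intervals, gene models and an expression count table.

    Repeat intervals for each category tile disjoint positions so the union
    size is exact (fraction × genome length, rounded down to whole
    intervals); when ``n_methods`` > 1 the same union is re-emitted as
    overlapping subsets so that cross-method union totals are known.
    Returns a dict with keys intervals (per method), gene_models, counts
    (genes × samples DataFrame), gene_lengths, mapped_totals and truth.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    G = genome.length
    intervals: dict[str, list[GenomicInterval]] = {}
    truth: dict = {"seed": seed, "unions": {}}
    if sum(cs.fraction for cs in category_specs) * G > G:
        raise ValueError("requested interval mass exceeds genome size")
    cursor = 0
    for cs in category_specs:
        n_iv = int(cs.fraction * G / cs.interval_length)
        if cursor + n_iv * cs.interval_length > G:
            raise ValueError("requested interval mass exceeds genome size")
        cat_ivs = []
        for _ in range(n_iv):
            cat_ivs.append(
                GenomicInterval(genome.id, cursor, cursor + cs.interval_length, cs.category)
            )
            cursor += cs.interval_length
        truth["unions"][cs.category] = n_iv * cs.interval_length
        for m in range(cs.n_methods):
            key = f"{cs.category}_method{m}"
            if cs.n_methods == 1:
                intervals[key] = list(cat_ivs)
            else:
                # overlapping halves: every method covers a random ~75% subset
                keep = rng.random(len(cat_ivs)) < 0.75
                keep[rng.integers(0, len(cat_ivs))] = True
                intervals[key] = [iv for iv, k in zip(cat_ivs, keep) if k]

    gene_models = []
    gene_span = exons_per_gene * exon_length + (exons_per_gene - 1) * intron_length
    gap_between = max(50, (G - cursor - n_genes * gene_span) // max(n_genes, 1))
    pos = cursor
    from .annotation_accounting import GeneModel

    for g in range(n_genes):
        if pos + gene_span > G:
            break
        exons = []
        e = pos
        for _ in range(exons_per_gene):
            exons.append((e, e + exon_length))
            e += exon_length + intron_length
        gene_models.append(
            GeneModel(f"gene_{g}", genome.id, pos, pos + gene_span, exons)
        )
        pos += gene_span + gap_between
    truth["gene_span"] = gene_span
    truth["mrna_length"] = exons_per_gene * exon_length
    truth["n_genes"] = len(gene_models)

    gene_ids = [m.gene_id for m in gene_models]
    counts = pd.DataFrame(
        rng.poisson(50, size=(len(gene_ids), n_samples)),
        index=gene_ids,
        columns=[f"sample_{s}" for s in range(n_samples)],
    )
    gene_lengths = pd.Series(
        {m.gene_id: m.mrna_length for m in gene_models}, name="length"
    )
    mapped_totals = pd.Series(
        rng.integers(5_000_000, 10_000_000, size=n_samples),
        index=counts.columns,
    ).astype(float)
    truth["rpkm"] = (
        counts.mul(1e9).div(gene_lengths, axis=0).div(mapped_totals, axis=1)
    )
    return {
        "intervals": intervals,
        "gene_models": gene_models,
        "counts": counts,
        "gene_lengths": gene_lengths,
        "mapped_totals": mapped_totals,
        "truth": truth,
    }
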