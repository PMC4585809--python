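"""Repeat, gene-model and expression-support accounting.

Covers three bookkeeping tasks of a genome-annotation report:

* non-redundant repeat totals — per annotation method and combined across
  methods by coordinate union, expressed as a percentage of the gap-free
  (contig) genome size;
* gene-model summary statistics — mean gene length (genomic span), mRNA
  length (exon sum), exons per gene, exon and intron length;
* RPKM expression support — reads per kilobase of gene model per million
  mapped reads, and the count/fraction of annotated genes exceeding RPKM
  thresholds per tissue sample and in any sample ("Combined").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import GenomicInterval
from .sequencing_effort import percent_of

DEFAULT_RPKM_THRESHOLDS = (0.0, 1.0, 5.0)
TANDEM_CATEGORY = "tandem"


# ---------------------------------------------------------------------------
# interval union

def merge_intervals(
    intervals: Sequence[GenomicInterval], by_category: bool = False
) -> tuple[list[GenomicInterval], int]:
    """Union overlapping or book-ended intervals per sequence (and per
    category when ``by_category``); returns merged intervals and their
    total length."""
    groups: dict[tuple, list[GenomicInterval]] = {}
    for iv in intervals:
        key = (iv.seq_id, iv.category) if by_category else (iv.seq_id,)
        groups.setdefault(key, []).append(iv)
    merged: list[GenomicInterval] = []
    total = 0
    for key in sorted(groups):
        ivs = sorted(groups[key], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        cat = ivs[0].category if by_category else ""
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(key[0], cur_start, cur_end, cat))
                total += cur_end - cur_start
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(key[0], cur_start, cur_end, cat))
        total += cur_end - cur_start
    return merged, total


# ---------------------------------------------------------------------------
# repeat ledger

@dataclass
class RepeatLedger:
    """Per-method, per-category and combined non-redundant repeat totals.

    Percentages are relative to ``genome_bases`` — by convention the
    assembly's gap-free (contig) base count.
    """

    genome_bases: int
    per_method: pd.DataFrame  # index method; columns bases, percent
    per_category: pd.DataFrame  # index category; columns bases, percent
    combined_te_bases: int = 0
    combined_all_bases: int = 0

    @property
    def combined_te_percent(self) -> float:
        return 100.0 * self.combined_te_bases / self.genome_bases

    @property
    def combined_all_percent(self) -> float:
        return 100.0 * self.combined_all_bases / self.genome_bases


def repeat_fractions(
    per_method_intervals: Mapping[str, Sequence[GenomicInterval]],
    genome_bases: int,
    tandem_methods: Sequence[str] = (),
) -> RepeatLedger:
    """Build the repeat ledger from per-method interval sets.

    Each method's total is the union of its own intervals; the combined TE
    total is the union across all methods except those named in
    ``tandem_methods``; the grand total additionally unions the tandem
    methods. The per-category table unions across methods within each
    category label.
    """
    if genome_bases <= 0:
        raise ValueError("genome_bases must be positive")
    method_rows = {}
    for method, ivs in per_method_intervals.items():
        _, bases = merge_intervals(ivs)
        method_rows[method] = {
            "bases": bases,
            "percent": 100.0 * bases / genome_bases,
        }
    te_ivs = [
        iv
        for method, ivs in per_method_intervals.items()
        if method not in tandem_methods
        for iv in ivs
    ]
    all_ivs = [iv for ivs in per_method_intervals.values() for iv in ivs]
    _, te_bases = merge_intervals(te_ivs)
    _, all_bases = merge_intervals(all_ivs)
    cat_merged, _ = merge_intervals(all_ivs, by_category=True)
    cat_rows: dict[str, dict] = {}
    for iv in cat_merged:
        row = cat_rows.setdefault(iv.category, {"bases": 0})
        row["bases"] += iv.length
    for row in cat_rows.values():
        row["percent"] = 100.0 * row["bases"] / genome_bases
    return RepeatLedger(
        genome_bases=genome_bases,
        per_method=pd.DataFrame.from_dict(method_rows, orient="index"),
        per_category=pd.DataFrame.from_dict(cat_rows, orient="index").sort_index(),
        combined_te_bases=te_bases,
        combined_all_bases=all_bases,
    )


def genome_percent(bases: int, genome_bases: int, decimals: int = 2) -> float:
    """Percentage of the genome occupied by ``bases``, printed-table style
    (round half-up)."""
    return percent_of(bases, genome_bases, decimals)


# ---------------------------------------------------------------------------
# gene models

@dataclass
class GeneModel:
    """One gene: transcript span on a scaffold plus its exon chain."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")

    @property
    def gene_length(self) -> int:
        return self.end - self.start

    @property
    def mrna_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def intron_lengths(self) -> list[int]:
        return [
            self.exons[i + 1][0] - self.exons[i][1]
            for i in range(len(self.exons) - 1)
        ]


def read_gene_models(gff3_path) -> list[GeneModel]:
    """Read gene/mRNA/exon features from GFF3 (one transcript per gene)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", force=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = [
            (exon.start - 1, exon.end)
            for exon in db.children(gene, featuretype="exon", order_by="start")
        ]
        models.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                exons=exons,
            )
        )
    return models


def write_gene_models(models: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 gene/mRNA/exon rows."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.seq_id}\tglk\tgene\t{m.start + 1}\t{m.end}\t.\t+\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.seq_id}\tglk\tmRNA\t{m.start + 1}\t{m.end}\t.\t+\t.\t"
                f"ID={m.gene_id}.t1;Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, start=1):
                fh.write(
                    f"{m.seq_id}\tglk\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID={m.gene_id}.e{i};Parent={m.gene_id}.t1\n"
                )


def gene_model_stats(models: Sequence[GeneModel]) -> dict:
    """Summary row: total genes, single-exon count, and means of gene
    length, mRNA length, exons per gene, exon length and intron length
    (introns pooled over all genes; None when every gene is single-exon)."""
    if not models:
        raise ValueError("no gene models")
    exon_lengths = [e - s for m in models for s, e in m.exons]
    intron_lengths = [L for m in models for L in m.intron_lengths]
    return {
        "total": len(models),
        "single_exon_genes": sum(1 for m in models if len(m.exons) == 1),
        "mean_gene_length": float(np.mean([m.gene_length for m in models])),
        "mean_mrna_length": float(np.mean([m.mrna_length for m in models])),
        "mean_exons_per_gene": float(np.mean([len(m.exons) for m in models])),
        "mean_exon_length": float(np.mean(exon_lengths)),
        "mean_intron_length": (
            float(np.mean(intron_lengths)) if intron_lengths else None
        ),
    }


# ---------------------------------------------------------------------------
# expression support

def rpkm(count: float, gene_length_bp: float, mapped_total: float) -> float:
    """Reads per kilobase of gene model per million mapped reads:
    count × 10^9 / (length × mapped_total)."""
    if gene_length_bp <= 0:
        raise ValueError("gene_length_bp must be positive")
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count * 1e9 / (gene_length_bp * mapped_total)


def rpkm_table(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    mapped_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene per-sample RPKM. ``counts`` is genes × samples;
    ``mapped_totals`` defaults to each sample's column sum."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("every gene needs a length")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if mapped_totals is None:
        mapped_totals = counts.sum(axis=0)
    mapped_totals = mapped_totals.reindex(counts.columns)
    if (mapped_totals <= 0).any():
        raise ValueError("mapped totals must be positive")
    return counts.mul(1e9).div(lengths, axis=0).div(mapped_totals, axis=1)


def support_ratios(
    rpkms: pd.DataFrame,
    total_annotated: int,
    thresholds: Sequence[float] = DEFAULT_RPKM_THRESHOLDS,
    decimals: int = 2,
) -> pd.DataFrame:
    """Per-sample and Combined counts/percentages of genes with RPKM
    strictly above each threshold.

    The Combined row counts genes exceeding the threshold in at least one
    sample. Percentages are of ``total_annotated`` (the full annotated gene
    set, which may exceed the table's rows).
    """
    if total_annotated <= 0:
        raise ValueError("total_annotated must be positive")
    rows = {}
    for sample in rpkms.columns:
        rows[sample] = {}
        for t in thresholds:
            n = int((rpkms[sample] > t).sum())
            rows[sample][f"n_rpkm_gt_{t:g}"] = n
            rows[sample][f"pct_rpkm_gt_{t:g}"] = percent_of(
                n, total_annotated, decimals
            )
    combined = {}
    for t in thresholds:
        n = int((rpkms > t).any(axis=1).sum())
        combined[f"n_rpkm_gt_{t:g}"] = n
        combined[f"pct_rpkm_gt_{t:g}"] = percent_of(n, total_annotated, decimals)
    rows["Combined"] = combined
    return pd.DataFrame.from_dict(rows, orient="index")
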