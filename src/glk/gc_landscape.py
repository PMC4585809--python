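"""Windowed GC composition, multi-scale SD curves, and chromosome-class /
genome-component GC breakdowns.

Isochore structure — long segments of homogeneous GC — shows up as window-GC
standard deviation that stays high as the window grows, whereas a
compositionally uniform (i.i.d.-like) genome decays as 1/sqrt(window size).
The SD-vs-scale curve therefore separates isochore from non-isochore
genomes; the ratio SD(largest)/SD(smallest) is used as a scalar "isochore
contrast".

Conventions: windows are non-overlapping, restart at each sequence's origin
and never span sequences; a trailing partial window is dropped; a window is
invalid when its non-ACGT fraction exceeds ``max_n_fraction``; the GC
denominator counts only A/C/G/T (ambiguity codes and N are excluded rather
than treated as AT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_io import GenomicInterval, GenomePartition, SequenceRecord

DEFAULT_WINDOW_SIZES = (5_000, 10_000, 20_000, 40_000, 80_000, 160_000, 320_000)
DEFAULT_MAX_N_FRACTION = 0.5


@dataclass
class GCWindowTrack:
    """Per-window GC fractions at one window size.

    ``records`` has columns seq_id, start, gc, valid; gc is NaN for invalid
    (N-rich) windows.
    """

    window_size: int
    records: pd.DataFrame

    def valid(self) -> pd.DataFrame:
        return self.records[self.records["valid"]]

    def to_tsv(self, path) -> None:
        df = self.records.copy()
        df["end"] = df["start"] + self.window_size
        df[["seq_id", "start", "end", "gc"]].to_csv(
            path, sep="\t", index=False, float_format="%.6f"
        )


@dataclass
class GCSummary:
    mean: float
    sd: float
    n_windows: int


@dataclass
class ScaleCurve:
    """SD of window GC at each window size (ascending)."""

    window_sizes: list[int]
    sds: list[float]

    def contrast(self) -> float:
        """Isochore contrast: SD at the largest scale over SD at the
        smallest; near 1 for block-isochore genomes, near
        sqrt(w_min / w_max) for uniform ones."""
        if self.sds[0] == 0:
            return float("nan")
        return self.sds[-1] / self.sds[0]


def _base_flags(seq: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
    return is_gc, is_acgt


def gc_fraction(seq: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); NaN when no unambiguous base."""
    is_gc, is_acgt = _base_flags(seq)
    denom = int(is_acgt.sum())
    return float(is_gc.sum()) / denom if denom else float("nan")


def window_gc(
    records: Sequence[SequenceRecord],
    window_size: int,
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
) -> GCWindowTrack:
    """Non-overlapping window GC across a sequence set."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if not 0 <= max_n_fraction <= 1:
        raise ValueError("max_n_fraction must be in [0, 1]")
    seq_ids: list[str] = []
    starts: list[np.ndarray] = []
    gcs: list[np.ndarray] = []
    valids: list[np.ndarray] = []
    for rec in records:
        nwin = rec.length // window_size
        if nwin == 0:
            continue
        is_gc, is_acgt = _base_flags(rec.seq[: nwin * window_size])
        gc_per = is_gc.reshape(nwin, window_size).sum(axis=1)
        acgt_per = is_acgt.reshape(nwin, window_size).sum(axis=1)
        valid = (window_size - acgt_per) <= max_n_fraction * window_size
        valid &= acgt_per > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            gc = np.where(valid, gc_per / np.maximum(acgt_per, 1), np.nan)
        seq_ids.extend([rec.id] * nwin)
        starts.append(np.arange(nwin, dtype=np.int64) * window_size)
        gcs.append(gc)
        valids.append(valid)
    if not starts:
        warnings.warn("window size exceeds every sequence; no windows emitted")
        frame = pd.DataFrame(columns=["seq_id", "start", "gc", "valid"])
    else:
        frame = pd.DataFrame(
            {
                "seq_id": seq_ids,
                "start": np.concatenate(starts),
                "gc": np.concatenate(gcs),
                "valid": np.concatenate(valids),
            }
        )
    return GCWindowTrack(window_size=window_size, records=frame)


def _filter_class(
    frame: pd.DataFrame,
    partition: GenomePartition | None,
    class_filter: str | None,
) -> pd.DataFrame:
    if class_filter is None:
        return frame
    if partition is None:
        raise ValueError("class_filter requires a partition")
    keep = frame["seq_id"].map(partition.classify) == class_filter
    return frame[keep]


def gc_summary(
    track: GCWindowTrack,
    partition: GenomePartition | None = None,
    class_filter: str | None = None,
) -> GCSummary:
    """Mean and sample SD (n−1) of GC over valid windows, optionally
    restricted to one chromosome class."""
    frame = _filter_class(track.valid(), partition, class_filter)
    n = len(frame)
    if n < 2:
        raise ValueError("need at least 2 valid windows for an SD")
    gc = frame["gc"].to_numpy()
    return GCSummary(mean=float(gc.mean()), sd=float(gc.std(ddof=1)), n_windows=n)


def sd_vs_scale(
    records: Sequence[SequenceRecord],
    window_sizes: Sequence[int] = DEFAULT_WINDOW_SIZES,
    partition: GenomePartition | None = None,
    class_filter: str | None = None,
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
) -> ScaleCurve:
    """SD of window GC at each window size (the isochore diagnostic curve)."""
    sizes = list(window_sizes)
    if not sizes or sizes != sorted(sizes):
        raise ValueError("window_sizes must be non-empty and ascending")
    sds = []
    for w in sizes:
        track = window_gc(records, w, max_n_fraction)
        sds.append(gc_summary(track, partition, class_filter).sd)
    return ScaleCurve(window_sizes=sizes, sds=sds)


def component_gc(
    records: Sequence[SequenceRecord],
    intervals: Sequence[GenomicInterval],
    partition: GenomePartition | None = None,
) -> pd.DataFrame:
    """GC per (chromosome class × annotation category).

    Overlapping intervals of one category are deduplicated by union before
    counting; bases covered by no interval at all are reported under
    category ``other``. Returns columns class, category, gc, bases (bases =
    unambiguous A/C/G/T bases counted in the denominator).
    """
    by_id = {rec.id: rec for rec in records}
    for iv in intervals:
        if iv.seq_id not in by_id:
            raise ValueError(f"interval references unknown sequence {iv.seq_id!r}")
        if iv.end > by_id[iv.seq_id].length:
            raise ValueError(
                f"interval {iv.seq_id}:{iv.start}-{iv.end} beyond sequence end"
            )
    categories = sorted({iv.category for iv in intervals})
    grouped: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        grouped.setdefault((iv.seq_id, iv.category), []).append(iv)
    # tallies[(class, category)] = [gc_count, acgt_count]
    tallies: dict[tuple[str, str], list[int]] = {}
    for rec in records:
        cls = partition.classify(rec.id) if partition else "unassigned"
        is_gc, is_acgt = _base_flags(rec.seq)
        any_mask = np.zeros(rec.length, dtype=bool)
        for cat in categories:
            mask = np.zeros(rec.length, dtype=bool)
            for iv in grouped.get((rec.id, cat), ()):
                mask[iv.start : iv.end] = True
            any_mask |= mask
            t = tallies.setdefault((cls, cat), [0, 0])
            t[0] += int(is_gc[mask].sum())
            t[1] += int(is_acgt[mask].sum())
        t = tallies.setdefault((cls, "other"), [0, 0])
        t[0] += int(is_gc[~any_mask].sum())
        t[1] += int(is_acgt[~any_mask].sum())
    rows = []
    for (cls, cat), (g, d) in sorted(tallies.items()):
        rows.append(
            {
                "class": cls,
                "category": cat,
                "gc": g / d if d else float("nan"),
                "bases": d,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plotting helpers (plain matplotlib; aesthetics are not a goal)

def plot_gc_distribution(tracks: dict[str, GCWindowTrack], path) -> None:
    """Overlaid window-GC densities, one labelled curve per genome/class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    bins = np.linspace(0.2, 0.7, 101)
    for label, track in tracks.items():
        gc = track.valid()["gc"].to_numpy()
        ax.hist(gc, bins=bins, density=True, histtype="step", label=label)
    ax.set_xlabel("GC fraction")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scale_curves(curves: dict[str, ScaleCurve], path) -> None:
    """SD-vs-window-size curves on a log x axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for label, curve in curves.items():
        ax.plot(curve.window_sizes, curve.sds, marker="o", label=label)
    ax.set_xscale("log")
    ax.set_xlabel("window size (bp)")
    ax.set_ylabel("SD of window GC")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)
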