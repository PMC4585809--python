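"""Canonical k-mer counting and k-mer-spectrum genome-size estimation.

A read set sequenced to depth *c* with reads of length *L* covers each
genomic position with only (L − k + 1)/L of its k-mer windows, so the modal
k-mer copy number underestimates the read depth. The estimator used here
corrects for that edge loss:

    depth = mode × L / (L − k + 1)
    genome size = total read bases / depth

In a diploid, heterozygous single-copy sequence yields k-mers present on one
haplotype only, producing a second spectrum mode at half the homozygous copy
number; mode detection therefore reports the error valley, the optional
heterozygous peak, and the homozygous peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

MAX_K = 31  # 2-bit packed k-mer must fit one 64-bit word
COPY_NUMBER_CEILING = 10_000  # deeper repeats collapse into one overflow bin

_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
    _CODES[_b + 32] = _i


@dataclass
class KmerSpectrum:
    """Histogram of distinct canonical k-mers per copy number."""

    k: int
    histogram: dict[int, int] = field(default_factory=dict)
    total_instances: int = 0

    def copy_numbers(self) -> np.ndarray:
        return np.array(sorted(self.histogram), dtype=np.int64)

    def to_tsv(self, path) -> None:
        """Two-column (copy_number, distinct_kmers) TSV, the dialect of
        standard k-mer counters' histogram export."""
        with open(path, "w") as fh:
            for cn in sorted(self.histogram):
                fh.write(f"{cn}\t{self.histogram[cn]}\n")

    @classmethod
    def from_tsv(cls, path, k: int) -> "KmerSpectrum":
        hist: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                cn, cnt = line.split()[:2]
                hist[int(cn)] = int(cnt)
        total = sum(cn * cnt for cn, cnt in hist.items())
        return cls(k=k, histogram=hist, total_instances=total)


@dataclass
class SpectrumModes:
    """Landmarks of a (possibly bimodal) k-mer spectrum.

    ``error_valley`` separates the low-copy sequencing-error spike from
    signal; ``het_mode`` (absent for effectively homozygous input) sits near
    half of ``hom_mode``. Modes are fractional: a parabola through the three
    histogram points around each integer peak refines its position.
    """

    error_valley: int
    hom_mode: float
    het_mode: float | None = None
    monotone_warning: bool = False

    @property
    def het_hom_ratio(self) -> float | None:
        if self.het_mode is None:
            return None
        return self.het_mode / self.hom_mode


def _encode_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical (min of forward / reverse-complement) 2-bit packed values
    of every fully-ACGT window of ``seq``."""
    codes = _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid_base = codes != 255
    bad = np.concatenate(([0], np.cumsum(~valid_base)))
    window_ok = (bad[k:] - bad[:-k]) == 0
    codes = np.where(valid_base, codes, 0).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    rc = np.uint64(3) - codes
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | codes[j : n + j]
        rev = (rev << np.uint64(2)) | rc[k - 1 - j : n + k - 1 - j]
    return np.minimum(fwd, rev)[window_ok]


def count_kmers(sequences: Iterable[str], k: int) -> KmerSpectrum:
    """Count canonical k-mers across ``sequences`` and histogram their
    copy numbers.

    Windows containing any non-ACGT character are skipped. Copy numbers
    above :data:`COPY_NUMBER_CEILING` are pooled into that overflow bin.
    """
    if not (1 <= k <= MAX_K):
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    # batch short reads into ~1 Mbp chunks joined by N so no window spans
    # a read boundary but numpy passes stay long
    parts: list[np.ndarray] = []
    buf: list[str] = []
    buf_len = 0
    for seq in sequences:
        buf.append(seq)
        buf_len += len(seq)
        if buf_len >= 1_000_000:
            parts.append(_encode_kmers("N".join(buf), k))
            buf, buf_len = [], 0
    if buf:
        parts.append(_encode_kmers("N".join(buf), k))
    if not parts:
        return KmerSpectrum(k=k)
    values = np.concatenate(parts)
    if values.size == 0:
        return KmerSpectrum(k=k)
    _, copy_numbers = np.unique(values, return_counts=True)
    total = int(values.size)
    clipped = np.minimum(copy_numbers, COPY_NUMBER_CEILING)
    cns, counts = np.unique(clipped, return_counts=True)
    hist = {int(cn): int(c) for cn, c in zip(cns, counts)}
    return KmerSpectrum(k=k, histogram=hist, total_instances=total)


def _dense_counts(spectrum: KmerSpectrum) -> np.ndarray:
    """Counts indexed by copy number (index 0 unused)."""
    top = max(spectrum.histogram)
    dense = np.zeros(top + 2, dtype=float)
    for cn, cnt in spectrum.histogram.items():
        dense[cn] = cnt
    return dense


def _smooth(dense: np.ndarray) -> np.ndarray:
    """Centered moving average of window 3; edges average what exists."""
    kernel = np.ones(3)
    num = np.convolve(dense, kernel, mode="same")
    den = np.convolve(np.ones_like(dense), kernel, mode="same")
    return num / den


def _parabolic_vertex(y: np.ndarray, i: int) -> float:
    """Refine an integer argmax to a fractional mode via the vertex of the
    parabola through (i−1, i, i+1). Falls back to i at the array edge or on
    a flat triple."""
    if i <= 0 or i >= y.size - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return float(i + 0.5 * (y[i - 1] - y[i + 1]) / denom)


def find_modes(spectrum: KmerSpectrum, min_copy_floor: int = 2) -> SpectrumModes:
    """Locate the error valley and the heterozygous/homozygous peaks.

    The histogram is smoothed (window-3 moving average); the error valley is
    the smallest copy number ≥ ``min_copy_floor`` that is a strict local
    minimum; the homozygous mode is the smoothed argmax beyond the valley
    (ties break toward the lower copy number); the heterozygous mode is the
    local maximum nearest hom/2 whose height exceeds the valley count. When
    the smoothed histogram has no interior local minimum the global argmax is
    reported with ``monotone_warning`` set.
    """
    if not spectrum.histogram:
        raise ValueError("cannot locate modes of an empty spectrum")
    dense = _dense_counts(spectrum)
    sm = _smooth(dense)

    valley = None
    for cn in range(max(1, min_copy_floor), sm.size - 1):
        if sm[cn] < sm[cn - 1] and sm[cn] < sm[cn + 1]:
            valley = cn
            break

    if valley is None:
        hom_i = int(np.argmax(sm[1:])) + 1
        warnings.warn("k-mer histogram is monotone; no error valley found")
        return SpectrumModes(
            error_valley=max(1, min_copy_floor),
            hom_mode=_parabolic_vertex(sm, hom_i),
            monotone_warning=True,
        )

    hom_i = int(np.argmax(sm[valley + 1 :])) + valley + 1
    hom_mode = _parabolic_vertex(sm, hom_i)

    interior = np.arange(max(1, min_copy_floor), sm.size - 1)
    is_max = (sm[interior] > sm[interior - 1]) & (sm[interior] >= sm[interior + 1])
    peaks = interior[is_max]
    peaks = peaks[(peaks < hom_i) & (sm[peaks] > sm[valley])]
    het_mode = None
    if peaks.size:
        cand = int(peaks[np.argmin(np.abs(peaks - hom_i / 2))])
        # accept only a peak plausibly at half copy number, not a repeat peak
        if 0.25 <= cand / hom_i <= 0.75:
            het_mode = _parabolic_vertex(sm, cand)
            if cand <= valley:
                # no sequencing-error spike below the het peak: the first
                # local minimum was the het-hom valley; move the error
                # valley below the het peak (or to the floor if monotone)
                below = None
                for cn in range(max(1, min_copy_floor), cand):
                    if sm[cn] < sm[cn - 1] and sm[cn] < sm[cn + 1]:
                        below = cn
                        break
                valley = below if below is not None else max(1, min_copy_floor)

    modes = SpectrumModes(error_valley=valley, hom_mode=hom_mode, het_mode=het_mode)
    ratio = modes.het_hom_ratio
    if ratio is not None and not (0.4 <= ratio <= 0.6):
        warnings.warn(
            f"het/hom mode ratio {ratio:.2f} outside [0.4, 0.6]; "
            "spectrum may not be a clean diploid"
        )
    return modes


def average_read_depth(mode: float, read_length: int, k: int) -> float:
    """Correct the modal k-mer copy number to a per-base read depth,
    mode × L / (L − k + 1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if read_length < k:
        raise ValueError("read_length must be >= k")
    if mode <= 0:
        raise ValueError("mode must be positive")
    return mode * read_length / (read_length - k + 1)


def estimate_genome_size(total_bases: float, depth: float) -> float:
    """Genome size = total read bases / average read depth."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if total_bases < 0:
        raise ValueError("total_bases must be non-negative")
    return total_bases / depth


def genome_size_from_spectrum(
    spectrum: KmerSpectrum,
    total_bases: float,
    read_length: int,
    min_copy_floor: int = 2,
) -> dict:
    """Convenience composition: find_modes → average_read_depth →
    estimate_genome_size. Returns the modes, depth and size in one record."""
    modes = find_modes(spectrum, min_copy_floor=min_copy_floor)
    depth = average_read_depth(modes.hom_mode, read_length, spectrum.k)
    size = estimate_genome_size(total_bases, depth)
    return {
        "k": spectrum.k,
        "error_valley": modes.error_valley,
        "het_mode": modes.het_mode,
        "hom_mode": modes.hom_mode,
        "average_read_depth": depth,
        "genome_size_bp": size,
    }
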