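# Methods

This note records the models, conventions and parameter choices behind
`glk`, and what the synthetic-data generators do and do not emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open; GFF3 and RepeatMasker
`.out` (1-based inclusive) are converted at the I/O boundary, so interval
length is always `end − start` and conversion round-trips are exact.
Strand is ignored throughout: every statistic in scope (GC, lengths,
repeat fractions) is strand-symmetric. Soft-masked (lowercase) FASTA input
is uppercased with the mask retained per base, and restored on write.
IUPAC ambiguity codes other than N are kept in sequences but treated as
"not A/C/G/T" by GC and k-mer logic, since there is no defensible single
assignment for them.

## k-mer spectrum and genome size

Canonical form is the lexicographic minimum of a window and its reverse
complement; windows containing any non-ACGT character are skipped.
k is limited to 31 so a 2-bit-packed k-mer fits one 64-bit word; the
histogram tail is pooled into an overflow bin at copy number 10,000, which
bounds memory without touching the single-copy modes.

Mode detection smooths the dense histogram with a centered moving average
of window 3 and uses the smoothed curve for all landmarks: the error
valley is the smallest copy number ≥ `min_copy_floor` (default 2, because
copy number 1 is dominated by sequencing error in real data) that is a
strict local minimum; the homozygous mode is the argmax beyond the valley,
ties breaking toward the lower copy number; the heterozygous mode is the
local maximum nearest half the homozygous mode whose height exceeds the
valley count, accepted only within 0.25–0.75 of the homozygous copy number
so repeat shoulders are not mistaken for a haplotype peak. In error-free
input there is no error spike, so the first local minimum can be the
het–hom valley; when the heterozygous peak falls at or below the detected
valley, the valley is re-sought below the peak (falling back to the
floor). Integer peaks are refined to fractional modes by the vertex of the
parabola through the three surrounding points — a declared, simple rule
that makes half-integer modes representable and reproducible. A spectrum
with no interior minimum is reported with a monotone-histogram warning. A
het/hom mode ratio outside [0.4, 0.6] triggers a diploid-consistency
warning rather than an error.

Depth correction and size estimation are exact arithmetic:
`depth = mode·L/(L−k+1)`, `size = total_bases/depth`. Both refuse
non-positive inputs and `L < k`.

## Sequencing effort

The picogram conversion constant is fixed at 0.978 × 10⁹ bp/pg (the
Doležel convention). Physical coverage `pairs × insert / genome` is the
idealized expectation for uniformly placed inserts; it is verified against
a circular mask-painting simulation, where the identity is exact. Printed-
table reproduction uses round-half-up at the displayed precision
(`percent_of`), with unrounded values always retained; Python's default
banker's rounding would disagree with printed tables on exact ties.

## Assembly statistics

Contigs are obtained by splitting scaffolds at maximal runs of at least
`min_gap_run` Ns. The default is 1 — every N is a gap — because that is
the only convention under which contig totals, scaffold totals and the gap
ratio are mutually consistent (contig + gap = scaffold bases exactly);
other assemblers' scaftig conventions (e.g. runs ≥ 10) are available via
the parameter. Nx sizes are computed on the descending cumulative sum
(first length at which the sum reaches x % of the total), each paired with
the cumulative sequence count. No minimum-length filter is applied before
Nx computation by default; the ≥100 bp and ≥2 kbp figures are reported
counts, not filters, and a `min_length` flag exists for the alternative
reading.

## GC landscape

Window GC is `(G+C)/(A+C+G+T)` — the denominator excludes N and ambiguity
codes so long assembly gaps do not deflate GC. Windows whose non-ACGT
fraction exceeds `max_n_fraction` (default 0.5) are invalid and carry no
value; trailing partial windows are dropped rather than rescaled so SDs at
one scale average equally-sized windows. SD uses the sample (n−1)
denominator. Windows restart at each sequence origin and never span
sequences, since scaffolds are independent coordinate systems. Multi-scale
curves default to the 5–320 kbp doubling ladder. For an i.i.d. sequence
with GC probability p the window SD has the binomial closed form
√(p(1−p)/W), which the tests use as an oracle, and the SD-vs-scale curve
decays as 1/√W; block-isochore sequence holds its between-block SD across
all scales smaller than the block length, so the contrast ratio
SD(320 kbp)/SD(5 kbp) cleanly separates the two regimes. Component GC
unions each category's intervals before counting (so duplicated
annotations are idempotent) and reports uncovered bases as category
`other`; the base-weighted average over a disjoint partition reconstructs
whole-sequence GC to floating-point accuracy.

## Annotation accounting

Repeat percentages use the gap-free (contig) base count as denominator —
the only denominator consistent with per-method and combined fractions on
a gappy assembly — configurable to scaffold totals. Per-method totals are
each method's own coordinate union; the combined TE total unions across
all non-tandem methods; the grand total additionally unions tandem
repeats. Gene length is the genomic span including introns and mRNA length
the exon sum (the only reading under which gene length far exceeds mRNA
length); intron means pool all introns of all genes and are reported as
absent when every gene is single-exon. RPKM thresholds are strict
inequalities, and the "Combined" support row uses the any-sample rule: a
gene counts if it exceeds the threshold in at least one sample.

## Synthetic data

Generators are pure functions of their explicit seeds (no global state)
and emit truth records sufficient to verify downstream statistics without
re-derivation. The diploid generator draws haplotype A from the GC model
and creates haplotype B by substituting bases at the requested
heterozygosity at uniformly chosen sites; the read simulator places reads
uniformly with substitution-only errors (no indels — sufficient for every
statistic in scope, not for aligner benchmarking). The isochore generator
defaults to 1 Mbp blocks at GC 0.35/0.55 in equal proportion and the
homogeneous model to p = 0.418, a realistic squamate genome-wide mean;
these defaults put the between-block SD at 0.10 and give the
plateau-vs-decay contrast at the standard window ladder. The assembly
generator draws geometric contig lengths joined by N runs and records
exact N50s, totals and gap ratio computed by direct enumeration at build
time.

What the generators do **not** emulate: base-quality profiles, GC-coverage
bias, indels, structural variation, transposon sequence realism, or
biologically realistic chromosome-scale GC gradients. Tests passing on
synthetic data therefore validate the *bookkeeping and estimators*, not
robustness to real-data artifacts such as mapping bias or library
chimerism.

## Problem sizes used in validation

The validation suite and reference-number script size their simulations to
what the statistics need, not more: parameter-recovery uses a 100 kbp
diploid at 30× (3 Mbp of reads, giving Poisson-tight spectrum modes);
isochore-contrast checks use 19.2 Mbp genomes so the largest (320 kbp)
window still has ~60 windows; binomial GC checks use 1–2 Mbp of i.i.d.
sequence. Published-table arithmetic (depth, size, percentages, gap
ratios) is exact at any size and uses the printed inputs directly.

## Known limitations

- The mode-refinement parabola is a declared convention; other tools'
  fractional modes may differ in the second decimal.
- The heterozygous-peak detector requires a genuine local maximum; at very
  low heterozygosity (≲ 0.2 % at 30×) the het shoulder merges into the
  homozygous peak and is correctly reported as absent.
- `count_kmers` is in-memory and comfortable to a few hundred Mbp of
  reads; it is not a disk-based counter for multi-Gbp read sets.
- Physical coverage is the idealized uniform-placement expectation and
  ignores read-length overlap conventions some pipelines subtract.
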