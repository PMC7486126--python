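# Methods

## The model

A dual-cassette splicing event consists of two adjacent cassette exons A1
and A2 between constitutive exons C1 and C2 (transcript orientation).  The
four possible isoforms — SKIP (−A), +A1, +A2, +A1A2 — each use a fixed set
of the event's six exon–exon junctions:

| junction | SKIP | A1 | A2 | A1A2 |
|----------|------|----|----|------|
| C1A1     | 0    | 1  | 0  | 1    |
| C1A2     | 0    | 0  | 1  | 0    |
| C1C2     | 1    | 0  | 0  | 0    |
| A1A2     | 0    | 0  | 0  | 1    |
| A1C2     | 0    | 1  | 0  | 0    |
| A2C2     | 0    | 0  | 1  | 1    |

Writing this 6×4 binary membership matrix as A and the isoform abundances
(in junction-read units) as x ≥ 0, the expected junction-read counts are
E[c] = A·x.  Given observed counts c, abundances are estimated by

    x̂ = argmin ‖A·x − c‖²

either unconstrained (`ls_clamp` mode: negatives are clamped to zero after
the fit) or subject to x ≥ 0 (`nnls` mode).  A has full column rank — each
isoform owns one junction unique to it (C1C2↔SKIP, A1C2↔A1, C1A2↔A2,
A1A2↔A1A2) — so the unconstrained minimiser is unique and a noiseless
count vector identifies x exactly.  Estimates are reported as fractions
f̂ = x̂/Σx̂ together with the PSI-like inclusion statistics

    inclusion(A1) = f(A1) + f(A1A2),   inclusion(A2) = f(A2) + f(A1A2).

### Model assumptions

* **Equal junction weights.**  The binary design assumes every junction of
  an isoform generates junction reads at the same rate.  With a fixed read
  length L and uniform coverage, each junction offers exactly L−1 spanning
  start positions per transcript copy, and sequencing yield per transcript
  is proportional to transcript length, so this holds and the estimator
  recovers *molar* isoform fractions without length correction.  Mixed
  read lengths across samples would violate it mildly; no per-junction
  weighting is applied.
* **Junction reads only.**  Exon-body reads carry isoform information
  (through exon inclusion) but are ignored: the estimator uses the six
  junction counts alone.
* **Unique mapping.**  Counts come from single-hit reads (NH == 1 when the
  tag exists, MAPQ ≥ 10 otherwise, both configurable); multi-mappers are
  discarded and tallied.

### Why clamp-then-normalise is the default

Fractions presuppose non-negative abundances, but the unconstrained fit
can return small negative components when counts are noisy or
inconsistent.  The default `ls_clamp` mode keeps the plain least-squares
fit (reported unclamped in `raw_abundance`, with its SSE) and clamps only
for normalisation; `nnls` is the statistically cleaner alternative and the
two agree exactly whenever the unconstrained solution is already
non-negative.  NNLS has one practically relevant advantage: when an
isoform has no supporting reads at all, its active constraint zeroes the
estimate exactly, so e.g. a pure +A1 sample reports inclusion(A1) = 1.0
exactly, while clamping can leave a dust-sized spurious component (~0.003
at 2000 reads).  Normalisation always divides by the clamped/NNLS
abundance sum, not the read total, so fractions sum to 1 by construction.

## Junction counting

Spliced alignments are read from SAM text (header optional; any iterable
of lines is accepted).  Each N CIGAR operation yields one observation
(donor = last aligned reference base before the gap, acceptor = first
after).  The anchor on each side is the number of aligned
reference-consuming bases (M/=/X/D) in the alignment segment bounded by
the read end or the neighbouring N; insertions and clips add no anchor.
An observation increments a junction when its gap matches exactly and both
anchors reach `min_overhang` (default 5 nt, a common junction-anchor
floor).  Gaps within ±2 nt of an event junction are tallied as near-misses
but never counted, to avoid silently absorbing mis-annotation.

A read spanning two event junctions — possible whenever a cassette exon is
shorter than the read, as with a 60-nt cassette and 100-nt reads —
increments both junctions by default (the convention junction tables use);
a count-once mode credits only the leftmost matched junction.  Counts are
invariant to read order, and raising `min_overhang` can only lower them.

Per-sample vectors are pooled by elementwise integer summation within
groups (replicates in bulk; cells of the same annotated type in
single-cell data).  Pooling before estimation is essential in the
single-cell regime: at a per-cell mean of ~2–5 junction reads most
individual cells fall below any sensible coverage floor, while a group of
200 cells yields ~10³ reads and a stable fit.

## Coverage QC

Groups with fewer than `min_total` (default 10) junction reads report
missing fractions with `qc_flag = low_coverage`; a non-trivial fit to a
handful of reads would be noise presented as signal.  An all-zero clamped
solution reports `degenerate`.  Degenerate and empty inputs never raise.

## Uncertainty

`bootstrap_fractions` resamples the observed total multinomially over the
observed junction proportions, re-estimates each replicate, and reports
2.5/97.5 percentile intervals, reproducible for a fixed seed.  Point
estimates remain the primary output.

## Synthetic data generator

The generator emulates the statistical structure of the real inputs at
three levels, with full ground-truth bookkeeping:

* **Bulk counts**: junction counts are multinomial draws of a fixed total
  (default depth 10⁴, within the realistic 10³–10⁵ junction-read range of
  pooled bulk data) over p = A·f/Σ(A·f), or independent Poissons.
* **Cell populations**: each cell's total is Poisson (default mean 5,
  matching the 0–20 junction reads a single cell contributes), then
  multinomial over its group's junction probabilities; a grouping table is
  emitted.
* **Spliced reads**: reads of length 100 are placed on a toy event with
  exon lengths C1 = 300, A1 = 60, A2 = 60, C2 = 300 (a 60-nt cassette is
  the size of a 20-residue insert and forces the dual-junction read path).
  An isoform is drawn per read with probability ∝ fraction × number of
  read placements (T − L + 1), the standard "reads ∝ molar abundance ×
  length" sequencing model; the start is uniform within the spliced
  transcript.  Under this model every junction offers L−1 placements per
  transcript, which is exactly the equal-weight assumption of the
  estimator, so estimation on simulated reads is unbiased.  Records carry
  NH:i:1 and CIGARs of the form xM..N..yM; exon-body reads are emitted too
  so the counter's ignore path is exercised.  The truth record tallies
  each emitted junction observation whose anchors reach
  `guaranteed_anchor` (default 5), so counting at `min_overhang = 5`
  must reproduce truth exactly — an integer, not statistical, check.

What the generator does *not* model: sequencing errors and quality
scores, read pairing, multi-mapping ambiguity, positional coverage bias,
mixed read lengths, or genes beyond the event.  Passing tests therefore
demonstrate correctness of counting, pooling and estimation given
well-formed alignments — not robustness to alignment artefacts, which
belongs to the upstream aligner.

## Numerical choices

* Unconstrained fits use `numpy.linalg.lstsq`; constrained fits use
  `scipy.optimize.nnls`.  Both are deterministic; the design is tiny and
  well-conditioned (λmax(AᵀA) = 4, λmin ≈ 0.76).
* No intercept by default: a constant junction-read background has no
  generative meaning for a single event.  `include_intercept=True` is
  available for comparison with generic regression workflows.
* Fractions-sum-to-one holds to 1e-9 by construction; noiseless recovery
  holds to 1e-9 in both modes.
* All randomness flows from one `numpy.random.default_rng(seed)` per
  generator call; no global state.
* Report floats are written with 6 significant digits and missing values
  as `NA`, so reports diff stably.

## Problem sizes used in the shipped checks

The test suite and the acceptance script regenerate all data at run time:
100 random abundance vectors per mode for noiseless recovery; 1000 random
integer count vectors (entries ≤ 10) for the NNLS-vs-grid cross-check
(grid step 0.05); 100 multinomial replicates at 5000 reads for parameter
recovery; 2 groups × 200 cells at mean depth 5 for the pooling workflow;
and 10 000 simulated reads for the SAM round trip.  These sizes give
comfortably reproducible statistics while keeping a full run in seconds.

## Known limitations

* One event at a time; no genome-wide discovery or multi-event batching.
* Single-end junction evidence only; mate-pair constraints unused.
* The uniqueness policy approximates aligner-specific "single hit"
  semantics, which vary; both NH and MAPQ routes are provided.
* Between-group differential-splicing testing is out of scope; the
  package reports per-group estimates (with optional bootstrap intervals)
  and leaves inference to the caller.
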