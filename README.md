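# dualcassette

Quantification of the four splice isoforms of a **dual-cassette-exon
event** from exon-junction read counts.

Neuroligin-1 (NLGN1) splice site A is the motivating example: two adjacent
cassette exons, A1 and A2, sit between constitutive exons C1 and C2, so a
transcript is one of four isoforms — −A (both skipped), +A1, +A2, or
+A1A2.  Which isoform dominates differs sharply between neuronal cell
types (the A1 insert is characteristic of GABAergic neurons) and changes
the protein's biochemistry: the 20-residue A1 insert carries 9
arginine/lysine residues and strengthens heparan-sulfate binding.
Quantifying the isoform mix per cell type, age or genotype from RNA-seq is
therefore the first analysis step, and that is what this package does —
for NLGN1 site A or any event with the same topology.

## The method

The event defines six exon–exon junctions (C1A1, C1A2, C1C2, A1A2, A1C2,
A2C2).  Each isoform uses a fixed subset of them, encoded in a 6×4 binary
design matrix **A** with column sums (1, 2, 2, 3).  With isoform
abundances **x** (junction-read units), expected junction counts are
**A·x**, so from an observed junction-count vector **c**:

1. **Count** reads spanning each junction from spliced SAM alignments
   (N CIGAR gaps, exact donor/acceptor match, anchors ≥ 5 nt, unique
   mappers only), or load pre-computed junction tables.
2. **Pool** counts across replicates, or across single cells of the same
   annotated type (pseudobulk) — single cells contribute only 0–20
   junction reads each, so pooling precedes estimation.
3. **Estimate** x̂ = argmin ‖A·x − c‖² (plain least squares with negatives
   clamped before normalisation, or NNLS), and report fractions
   f̂ = x̂/Σx̂.
4. **Summarise** inclusion: PSI-like statistics
   inclusion(A1) = f(A1) + f(A1A2) and inclusion(A2) = f(A2) + f(A1A2).

Because each isoform owns one junction unique to it, **A** has full column
rank and noiseless counts identify the isoform mix exactly.  A synthetic
data module generates junction counts, sparse cell populations, and
spliced SAM reads from known mixtures with exact ground-truth records, so
the whole pipeline is testable without any external download.  See
`docs/methods.md` for the model, assumptions and design choices.

## Worked example

Simulate two cell populations of 200 cells (mean 5 junction reads per
cell) — one GABAergic-like mix (20% −A, 50% +A1, 5% +A2, 25% +A1A2), one
glutamatergic-like (90% −A, 5% +A1, 5% +A1A2) — then pool and estimate:

```yaml
# event.yaml — the built-in toy geometry (1-based inclusive coordinates)
event_id: toy
chrom: chrT
strand: '+'
c1_start: 1
c1_end: 300
a1_start: 401
a1_end: 460
a2_start: 561
a2_end: 620
c2_start: 721
c2_end: 1020
```

```bash
dualcassette simulate-cells \
    --group gaba_like=0.2,0.5,0.05,0.25 \
    --group glut_like=0.9,0.05,0,0.05 \
    --n-cells 200 --depth-mean 5 --seed 7 \
    --out-counts cells.tsv --out-groups groups.tsv

dualcassette run --event event.yaml \
    --counts cells.tsv --groups groups.tsv --out report.tsv
```

`report.tsv` (columns abridged):

```
group_id   n_samples  total_junction_reads  frac_skip  frac_a1    frac_a2    frac_a1a2  inclusion_a1  qc_flag
gaba_like  200        1054                  0.183752   0.518859   0.0623791  0.23501    0.753868      ok
glut_like  200        1012                  0.899617   0.0461451  0          0.0542383  0.100383      ok
```

Each row is one pooled group: the six junction counts (not shown), the
estimated isoform fractions, and the A1-inclusion statistic.  The
estimates recover the generating mixtures to ~0.02 and reproduce the
cell-type contrast (A1 inclusion 0.75 vs 0.10).  Groups with fewer than
10 pooled junction reads report `NA` fractions with `qc_flag
low_coverage` instead of a meaningless fit.

The same pipeline runs from alignments (`--sam sample1=s1.sam ...`), and
every stage is available separately (`count`, `pool`, `estimate`,
`simulate-counts`, `simulate-reads`) or as library calls, including a
scikit-learn transformer:

```python
from dualcassette import IsoformAbundanceEstimator
import numpy as np

X = np.array([[395, 31, 95, 115, 263, 155]])   # one row per group
est = IsoformAbundanceEstimator().fit(X)
est.transform(X)        # -> [[0.1838, 0.5189, 0.0624, 0.2350]]
```

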