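# abscount

Read processing and cohort statistics for single-cell multi-omics
(AbSeq-style antibody tags + targeted mRNA panel) sequencing, from paired
FASTQ to a corrected cells × features count matrix — with a ground-truthed
read simulator for validating every stage.

The package is aimed at people analysing bead-based targeted single-cell
assays (BD Rhapsody-like chemistry) who want an open, testable
re-implementation of the vendor-style primary analysis: each R1 read carries
a three-part cell label (CLS1/CLS2/CLS3, each one of 96 whitelisted 9-mers
at fixed positions 1–9, 22–30, 44–52), an 8-nt UMI, and a poly(T) tail; each
R2 carries a fragment of one of ~300 panel amplicons (mRNA targets and
antibody tags) or of a phiX decoy.

## What it does

1. **Read QC** — drop pairs with R1 < 66 nt or R2 < 64 nt, mean Phred < 20
   on either mate, or single-nucleotide frequency (fraction of the read that
   is its most common base) ≥ 0.55 (R1) / ≥ 0.80 (R2).
2. **Cell-label annotation** — perfect whitelist matches at the designed
   offsets; otherwise recovery of single substitutions (unambiguous because
   whitelists keep pairwise Hamming distance ≥ 3) and of a single
   insertion/deletion via shifted-frame re-testing. UMIs with N or a failed
   poly(T) check (> 6 of the 8 bases after the UMI must be T) invalidate the
   read.
3. **Panel alignment** — built-in seed-and-extend ungapped aligner; a read
   is valid only if it maps uniquely to one panel feature, the alignment
   starts within the first five read bases, spans > 60 columns, and does not
   hit the decoy.
4. **Molecule counting** — reads sharing (cell label, UMI, feature) collapse
   into one molecule whose depth is its read count; then two corrections:
   **RSEC** (recursive substitution error correction) merges each UMI into a
   strictly deeper Hamming-1 neighbour, recursively, so sequencing errors in
   UMIs rejoin their parent molecule; **DBEC** (distribution-based error
   correction) fits per feature a two-component geometric mixture over
   molecule depths by exhaustive split-threshold search and removes the
   low-depth component when the component means differ ≥ 4-fold.
5. **Cell calling** — labels sorted by read count; on the log₁₀ cumulative
   read curve the label rank at the curvature minimum (the "knee") separates
   cell-derived labels from ambient noise labels.
6. **Matrix export** — CellRanger-like `matrix.mtx` / `features.tsv` /
   `barcodes.tsv` triplet, mRNA and protein features side by side with a
   feature-type tag; `CountMatrix.to_anndata()` for scanpy users.
7. **Cohort statistics** — per-cluster cell proportions by group, fold
   changes (reported to one decimal), and a two-sided two-proportion z-test
   (Fisher's exact as an alternative), with optional Benjamini–Hochberg
   correction. Cluster assignments are an input column; clustering itself is
   out of scope.
8. **Simulator** — generates the full read anatomy with configurable error
   processes (CLS substitutions, linker indels, UMI substitutions, R2
   substitutions, ambient decoy reads, low-quality reads), a two-population
   (cell vs noise) depth distribution, case/control cohorts with shifted
   subpopulation proportions, and a complete ground-truth ledger.

## Worked example

```bash
python examples/simulate_and_count.py
```

prints (exactly, it is fully seeded):

```
simulated 75485 read pairs, 10581 true molecules
QC kept 75485/75485 reads; valid pairs 75485
molecules: 15097 raw -> 15097 corrected
cells called: 200 (inflection rank 200)
matrix equals truth exactly: True
```

An error-free run of 200 cells over a 30-feature panel (plus 2000 ambient
noise labels) is reconstructed perfectly: the knee lands exactly at rank
200, the 4516 noise-label molecules are excluded by cell calling, and the
output matrix equals the simulator's truth matrix entry for entry.

The proportion statistics reproduce the published cluster shifts they were
modelled on:

```python
>>> from abscount import fold_change
>>> fold_change(30.35, 9.38)   # effector T-cell cluster, case vs control
3.2
>>> fold_change(2.11, 0.62)
3.4
```

Other examples: `examples/barcode_recovery.py` (substitution and indel
repair on a single read), `examples/knee_calling.py` (analytic and
stochastic knees), `examples/cohort_proportions.py` (full case/control
table on a simulated cohort).

A thin CLI wraps the same library: `abscount simulate | run | callcells |
stats` (see `abscount --help`).

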