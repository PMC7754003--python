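# Methods

This note documents the models, algorithms and numerical choices behind
`abscount`, what the simulator does and does not emulate, and the
limitations a user should know about.

## Read anatomy and coordinate conventions

R1 is modelled as CLS1 (9 nt) + L1 (12 nt) + CLS2 (9 nt) + L2 (13 nt) +
CLS3 (9 nt) + UMI (8 nt) + poly(T). In 1-based coordinates the CLS
sections occupy positions 1–9, 22–30 and 44–52 and the UMI 53–60;
internally everything is 0-based half-open ([0,9), [21,30), [43,52),
[52,60)). The simulated poly(T) tail is 10 nt — longer than the 8 bases
the poly(T) check inspects — so default R1 length is 70 nt, comfortably
above the 66-nt QC floor.

## QC filters

Single-nucleotide frequency (SNF) is defined as the count of the read's
most frequent base divided by read length; no exact formula is standard,
and this is the natural reading of a low-complexity screen. SNF bounds
are *inclusive* (a read at exactly 0.55/0.80 is dropped), matching how
the thresholds are conventionally printed (≥). Mean quality is tested
per mate and the pair dropped if either fails — the stricter reading of
a per-"read score" rule. SNF is computed over the full read with no
trimming, so genuinely poly(T)-heavy R1s can fail it; that is the
filter's purpose. The undefined "R1/R2 ratio" filter sometimes listed
alongside these has no stated semantics and is not implemented.

## Cell-label recovery

Whitelists are generated (the vendor's are proprietary) by rejection
sampling 96 9-mers per section at pairwise Hamming distance ≥ 3. That
distance guarantee makes radius-1 Hamming balls disjoint, so
single-substitution correction is a constant-time dictionary lookup and
is provably unambiguous.

Recovery proceeds from a perfect-match fast path; failing that, all
repair hypotheses are enumerated and scored:

* the unshifted frame with ≤ 1 substitution per section
  (cost = number of substitutions);
* ten shifted frames — one ±1 shift applied from each of the five
  segment boundaries, modelling a single insertion or deletion anywhere
  in the label region (cost = 1 + substitutions).

The minimal-cost hypothesis wins; if distinct label triples tie at
minimal cost the read is dropped rather than guessed. Early-exit
variants (accept the first resolving frame) were measurably unsound: a
shifted window is effectively a random 9-mer and falls inside *some*
entry's Hamming-1 ball with probability ≈ 1 %, so on indel-carrying
reads the first resolving frame is occasionally the wrong one.
Min-cost selection with tie-dropping achieves, on simulated reads with
5 % CLS substitution and 1 % linker indel rates, ≥ 99 % recovery of
corrupted reads with zero misassignments (measured against the
simulator's ledger by the acceptance suite).

An indel *inside* a CLS section is not recoverable by any shifted-frame
hypothesis (the 9-mer window can no longer Hamming-match), and such
reads are correctly dropped as unresolved.

The poly(T) verdict requires more than 6 of the 8 bases after the UMI to
be T (i.e. ≥ 7 of 8); the window shrinks on truncated reads
(tolerating one non-T) and fails below 6 bases. The tolerated non-T
count is configurable (`polyt_max_non_t`) since "at least 6 of 8" is a
plausible alternative reading of the rule.

## Panel alignment

The aligner is deliberately minimal: exact k-mer seeds (default k = 18,
short enough that any valid ≥ 61-column alignment contains a seed, long
enough that random collisions on a ≤ 300-feature panel are negligible)
taken at read offsets 0–4 — so any alignment allowed to start within
the first five bases is seedable — and every k/2 stride thereafter.
Each (feature, diagonal) candidate is extended ungapped over the full
overlap; score = matches − mismatches; candidates with > 10 % mismatches
are discarded; N never matches. Gapped alignment is unnecessary because
validity counts only match/mismatch columns.

Uniqueness uses a score margin (default 3): any second feature scoring
within the margin of the best makes the read non-unique. Validity rules
apply in fixed order — decoy, uniqueness, start offset ≤ 4 (0-based),
span > 60 — and any viable decoy alignment invalidates the read even
when a panel feature scores higher. The order of the decoy and
uniqueness checks is a design choice; tests pin it.

Equivalence with a brute-force all-offset scan (same best feature,
span, score, decoy verdict) is asserted on 1000 randomized reads in the
test suite.

## Molecule collapsing, RSEC, DBEC

Collapsing counts one molecule per distinct (cell label, UMI, feature)
with depth = contributing reads; total depth always equals retained
pairs.

**RSEC** operates within each (cell, feature) group on the graph of
UMIs at Hamming distance exactly 1. Repeatedly, the lowest-depth UMI
having a strictly deeper neighbour merges into its deepest such
neighbour (ties broken lexicographically), adding depths; merging
re-evaluates the graph, so chains collapse recursively toward the
deepest parent. Strictly-greater depth is required to define direction;
equal-depth pairs stay unmerged (no defensible parent). The
lowest-depth-first order matters: merging an intermediate chain node
first would strand its children, so the ordered rule is part of the
algorithm's definition, and the test oracle enumerates merge orders
under exactly that rule.

**DBEC** is a published method name whose parametric internals are not
public; the implementation here is an explicit, documented model:
per feature (across cells), molecule depths are split at the threshold
t maximizing the summed log-likelihood of two geometric components
(each fit by moments, p = 1/mean) over all candidate splits — a
brute-force search, not EM, so the optimum is exact and deterministic.
Molecules with depth ≤ t are removed only when the component means
differ by ≥ 4-fold (`dbec_min_fold_separation`); otherwise the
distribution is treated as unimodal and untouched. Features with fewer
than 20 molecules (`dbec_min_group`) pass through, as mixture fits on
tiny groups are meaningless. The geometric family suits read-depth data
(positive, integer, overdispersed toward 1 for artifacts); all three
knobs are config-exposed.

Correction order is fixed: collapse → RSEC → DBEC → cell calling.

## Knee-point cell calling

Labels are sorted by descending read count (ties lexicographic, for
determinism) and the cumulative read sum is taken on log₁₀ axes (log
rank vs log cumulative reads — the conventional knee-plot geometry; the
upstream description fixes only the y transform). The inflection is the
minimum of the *change in secant slope*: at rank i, the slope over the
next h ranks minus the slope over the previous h ranks, with
h = `smooth_window` // 2 (default window 15). Two alternatives were
evaluated and rejected on fixtures with known answers:

* moving-average smoothing followed by narrow central differences
  delocalizes the minimum (rank 106 instead of 100 on a two-plateau
  curve; 494–497 instead of 500 on lognormal mixtures) because the
  smoothing smears the kink;
* the fully normalized second derivative (dividing the slope change by
  the local log-rank spacing) amplifies the tail, where spacing shrinks:
  with quantized read counts (constant reads per molecule) a 10 → 5-read
  plateau boundary deep in the noise outscored the true knee.

The un-normalized slope change is a curvature estimate up to a slowly
varying positive factor, is exact on the two-plateau fixture (rank 100),
calls 500/500 on lognormal mixtures across seeds, and is scale-invariant
(multiplying all counts shifts the curve vertically only). The argmin
excludes the first and last `smooth_window` ranks to avoid boundary
artifacts. If the statistic's range is below 1e-9 (e.g. all counts
equal) the curve is flagged degenerate and nothing is called. A
first-derivative variant is available (`derivative_mode="first"`).

Cell calling runs on per-label read counts of retained pairs (reads,
not molecules), matching the cumulative-reads curve definition.

## Cohort statistics

Proportions are per-group cluster fractions in percent (two decimals,
as conventionally printed); fold change is the case/control percentage
ratio reported to one decimal, undefined (NaN) for a zero denominator.
The significance test behind published per-cluster stars is typically
unnamed; both a two-sided two-proportion z-test (default) and Fisher's
exact test are provided and labelled in the output. No multiple-testing
correction is applied by default; Benjamini–Hochberg is a flag.
Cluster assignments are consumed as a column — graph clustering, CCA
integration and differential expression are out of scope.

## Simulator: what it emulates, what it does not

The generator emulates: the full R1 anatomy; R2 as a ≥ 61-nt substring
of a countable feature (or of the decoy at a configurable ambient
rate); a two-population depth model (reads per label lognormal —
default cells ~ LogNormal(ln 250, 0.25), ambient labels ~
LogNormal(ln 10, 0.5), so cell calling faces a realistic but separable
knee); per-cell molecule allocation across features (uniform by
default, configurable rates); case/control cohorts with shifted
subpopulation proportions (defaults mirror a 30.35 % vs 9.38 % and a
2.11 % vs 0.62 % cluster shift, remainder in a background pool); and
per-read error processes with a complete ledger of every injected
error and its read's true origin.

Deliberate simplifications, and hence what passing tests do *not*
demonstrate about real data:

* reads per molecule is a constant (default 5), not a PCR amplification
  distribution — closure tests therefore prove pipeline correctness,
  not robustness to amplification skew;
* UMIs are drawn uniformly from 4⁸ but without replacement within a
  (cell, feature) group: a within-group collision is indistinguishable
  from a single molecule *by any method*, so allowing them would make
  even a perfect pipeline fail exact-closure checks; real collision
  probability at these molecule counts is ≪ 1 per run;
* CLS substitutions are injected inside CLS windows and indels inside
  the linkers — the placement the recovery model is designed for;
  indels inside CLS sections occur in reality and are unrecoverable by
  design (dropped, not misassigned);
* UMI errors are single substitutions, matching RSEC's Hamming-1
  assumption; deletion-type UMI errors are only covered indirectly via
  DBEC's depth model;
* no PCR chimeras, doublets, cycle-dependent quality decay, or
  cell-to-cell expression structure beyond the subpopulation label.

Quality strings are constant Phred+33 (Q30; a configurable fraction of
Q15 "bad" reads exercises the mean-quality filter). FASTQ output is
gzip with zeroed mtime, so identical config + seed reproduces
byte-identical files.

## Problem sizes

Validation scenarios are sized to exercise every code path while
keeping the full suite fast: the closure run uses 200 cells × 30
features with 2000 ambient labels (~75 k read pairs), error-recovery
runs use ~30–40 k pairs, and knee accuracy uses 500 cells vs 5000
ambient labels over five seeds. These are an order of magnitude below a
real 10 000-cell experiment in cells but not in per-cell depth; the
per-read algorithms are O(1) in cohort size and the pipeline processes
~15 k pairs/s in pure Python, so scaling to real runs is a matter of
patience, not correctness.

## Known limitations

* The aligner is ungapped by design; R2 indels make a read invalid
  (span collapses below the 60-column rule) rather than recovered.
* DBEC's geometric mixture is a stand-in for an unpublished method;
  with strongly non-geometric depth distributions the 4-fold separation
  guard errs toward keeping molecules.
* The knee caller assumes a single inflection; multi-modal depth
  distributions (e.g. strong doublet populations) are flagged only if
  globally degenerate.
* Whitelist generation is synthetic; processing real instrument data
  requires supplying the instrument's actual 96-sequence lists and
  linkers in the whitelist directory.
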