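# Methods

This note documents the models, conventions and parameter choices behind
`barrierscreen`, in the order the pipeline runs them.

## Library design

Candidates come in three classes: CTCF-binding sequences carrying an
affinity score (higher = stronger predicted binding), MIR retrotransposons
with genomic intervals, and random DNA controls. Selection rules:

* **Ranking.** `rank_select` orders by score (descending for top-k,
  ascending for bottom-k) with ties broken by lexicographic id, so the
  selection is a pure function of the candidate set. The default quotas
  are 450 high-affinity + 50 low-affinity CTCF sites, 30 LAD-boundary
  MIRs, 420 other MIRs, 50 random controls (1000 total).
* **LAD proximity.** Coordinates are 0-based half-open (BED). The distance
  from an element to a LAD boundary is the gap between the interval and
  the boundary *coordinate* (a LAD's start or end): `max(boundary − end,
  start − boundary, 0)`. "Near" means strictly `< 5000` bp on the same
  chromosome. An element spanning a boundary has distance 0; an element
  deep inside a LAD gets its distance to the nearer edge and is therefore
  *far*.
* **Length adjustment.** Cores are the centered 250 bp window; an odd
  excess leaves the extra base on the 5′ side (for a 251 bp candidate the
  window is [0, 250)). Candidates shorter than the core length are dropped
  with a warning and back-filled from the next eligible candidate — the
  library is strictly uniform-length by construction.
* **Flanks and exclusion.** 50 bp of cloning flank is split 25 + 25 around
  the core (only the total is externally constrained; the even split is
  this package's convention), giving 300 bp oligos. The Esp3I/BsmBI
  recognition site (`CGTCTC`) and its reverse complement are excluded from
  the *entire* oligo, since a site on either strand breaks Golden Gate
  cloning. Random sequences are rejection-sampled (cap: 10,000 attempts
  per sequence) to be site-free.
* **Coverage arithmetic.** `expected_clones(n_transfections, cells,
  efficiency)` is their product rounded to the nearest integer;
  `fold_coverage(cfu, N)` is a plain ratio. Both are linear in their count
  arguments.

## The synthetic screen

### Silencing model

Each element has a latent barrier strength `b ∈ [0, 1]` driving two
superposed per-cell processes at a heterochromatic reporter:

* all-or-none shutdown with hazard `λ = λ_max (1 − b)` per day — a cell is
  OFF by day *t* with probability `1 − e^(−λt)` and then draws its
  intensity from the autofluorescence distribution;
* graded decay of ON cells, `I(t) = I0 · e^(−kt) · ε`, with
  `k = k_max (1 − b)` and `ε` lognormal cell-to-cell noise.

Whether the dim EGFP⁺ population seen in such reporters is a discrete
state or a continuous decay is not established; this model takes the
continuous-decay view and keeps a comparatively small all-or-none hazard.
Under the defaults (`λ_max = 0.03`/day, `k_max = 0.6`/day) an unprotected
reporter at day 15 is ~36% discretely OFF while its remaining ON cells
have decayed below the autofluorescence boundary — the population reads as
essentially fully EGFP-negative, with a distinct dim EGFP⁺ population at
intermediate times, and the population MFI decays exponentially.

Parameters (defaults, units, why):

| parameter | default | meaning / rationale |
|---|---|---|
| `λ_max` | 0.03 /day | all-or-none hazard of an unprotected element; see above |
| `k_max` | 0.6 /day | intensity decay of unprotected ON cells; calibrated so partially protective elements (b ≈ 0.55–0.85) span the Low/Medium gates at day 15 and only b ≳ 0.85 stays High |
| `I0` | 10,000 a.u. | baseline ON intensity |
| cell noise σ | 0.3 (ln-scale) | lognormal expression noise |
| autofluorescence | median 30, σ 0.4 | OFF-cell intensity; >99.9% below the Negative gate edge |
| gates | 150, then log-spaced tertiles to 10⁴ | Negative edge at the autofluorescence boundary; the true sorter coordinates of any given instrument are not reconstructed |
| background b | 0.55 + 0.3·Beta(3, 2) | the library is designed from candidates predicted to be at least partially functional, so most members confer partial protection |
| strong / null b | U(0.9, 1.0) / 0 | planted positives and inert controls (by default the 50 random-sequence controls are the nulls) |

The regime was fixed by a design-time power analysis: with only two
replicates per group, a Welch t-test at α = 0.05 needs a per-element
noncentrality near 20 to call hits reliably, which requires the Negative
gate to be dominated by truly inert elements and the High gate by strong
barriers. A screen whose readout cannot separate its own planted
phenotypes would be a badly designed screen; the defaults describe a
well-powered one.

### From cells to reads

Cells are simulated per element (counts scaled by the plasmid-pool weight
of the element, so clone-number imbalance propagates), gated with
half-open boundaries `[lower, upper)`, and each gate is sequenced to a
fixed read total: element read counts are multinomial with probabilities
proportional to (cells in gate) × lognormal PCR jitter (σ = 0.05,
a well-optimized amplicon PCR). Each read is a shared linker plus a
uniformly placed window of the element's 300 bp oligo on either strand,
with per-base substitution (10⁻³) and indel (10⁻⁴) errors and Gaussian
Phred qualities (36 ± 2) — a MiSeq-like 2×250 profile. The pDNA pool is
drawn once per screen as gamma weights (squared CV = 0.01) with 1.5%
dropout, and sequenced as **two technical replicates** of the same pool,
mirroring the practice of treating the forward and reverse reads of one
pDNA sample as replicates. Biological replicates of sorted samples differ
by independent cell populations and sampling noise (fresh RNG streams);
a ground-truth manifest records `b`, `λ`, `k`, `I0`, pool weights and the
realized gate-frequency matrix.

### What the generator does not emulate

Integration-site position effects, clonal expansion dynamics, sorter
impurity/spillover between gates, index hopping, PCR chimeras, and
contamination events. Replicate correlations are consequently higher
(≈0.98 on log abundance) than the ≈0.8 a real screen reports, and the
day-14 MFI fold changes between protected and unprotected reporters are
larger than real instruments show (the synthetic dynamic range
I0/autofluorescence ≈ 300 is not calibrated to a cytometer). Passing
tests therefore demonstrate correctness of the *analysis* under the
stated statistical structure, not robustness to every artifact of real
data.

## Read mapping

* **Trimming.** The shared linker is removed on an exact prefix match,
  else on the longest suffix-of-linker = prefix-of-read overlap of ≥8 bp.
  Quality trimming scans 4-base windows *ending* at each position
  (partial windows at the 5′ start) and truncates before the first
  position whose window mean is ≤ 25.75; the threshold follows the
  upstream QC convention, the window rule is this package's (the QC tool
  that reports the threshold does not itself trim).
* **Alignment.** Smith–Waterman with affine gaps (match +2, mismatch −3,
  gap existence 5, gap extension 2 — BLASTN-like), both strands, floor =
  the score of a 20 bp exact match. Mismatches and gap columns (inserted
  + deleted bases, BLAST tabular semantics) come from the traceback;
  `mapped_length` is the element span `r_end − r_start`. The kernel is
  numba-compiled; tie preferences (diagonal > read-gap > element-gap,
  open > extend, earliest best cell) are fixed so results are
  deterministic and oracle-checkable. `evalue_proxy = e^(−score) ×
  (library bp × read bp)` is a ranking proxy only, *not* a calibrated
  Karlin–Altschul E-value; it underflows to 0 for long perfect matches,
  which is harmless for ordering.
* **Candidate shortlisting.** For whole-sample mapping a 16-mer index
  shortlists (element, strand) pairs by sampled k-mer votes, keeping
  those with at least half the best vote — shared flanks hit every
  element but only the true source dominates the vote. Shortlisted pairs
  are aligned with the identical kernel, so shortlisting changes *which*
  alignments are computed, never their values; agreement with the
  exhaustive path is property-tested.
* **Deduplication and filters.** One alignment per read: highest score,
  then lowest e-value proxy, then lexicographically smallest element id.
  Filters: mismatches ≤ 3, gap columns ≤ 3, mapped length ≥
  `min(trimmed read length, oligo length) − 10`. Per-rule rejection
  counters are kept.

## Enrichment

Abundance is `100 × count / column total` (columns with zero totals are
flagged undefined, not errors). Fold change adds a pseudocount of 0.005
percentage points — small against typical abundances of ~0.1% but enough
to keep pDNA dropouts finite — to both numerator and denominator means.
The replicate test is Welch's (unequal variances); with two replicates
per group a pooled test would be no more stable and the unequal-variance
form is the safer default. Degenerate inputs are explicit: both groups
constant and equal → p = 1; both constant but different → p undefined and
the element is called *undetermined*. By default the test runs on
`log10(abundance + pseudo)`: replicate SDs on the raw percent scale grow
with the mean, which collapses the Welch degrees of freedom toward 1 at
n = 2, while log abundances are approximately homoskedastic (the usual
practice in count-based screens). Calls use strict inequalities
(enriched: FC > 1.5 and p < 0.05; depleted: FC < 0.67 and p < 0.05). No
multiple-testing correction is applied by default, matching the
screening convention of validating hits individually; a
Benjamini–Hochberg helper exists. Replicate correlation is Pearson on
`log10(abundance + pseudo)` unless raw scale is requested.

## Sequence features

Motif counts are overlapping start positions of an IUPAC pattern
(`GGGGG` contains two `GGGG` sites); this matters for run-like motifs and
is stated rather than hidden. The VEZF1 G-tract is counted on the given
strand only by default (the motif is written 5′-GGGG-3′), with an opt-in
both-strands mode that suppresses double-counting for
reverse-complement-palindromic patterns — `CANNTG` is its own reverse
complement, so its count is strand-invariant by construction. GC content
excludes ambiguous bases from numerator and denominator. Information
content per PFM column is `2 + Σ f log2 f` with `0·log 0 ≡ 0` and no
small-sample correction; box statistics use linear interpolation between
order statistics (so the quartiles of {1,2,3,4} are 1.75 and 3.25).

## Flow kinetics

Bead normalization multiplies the sample MFI by
`beads_dayn / beads_day1`, exactly as the published formula is printed,
with day 1 as the reference. Scaling a sample *up* when beads read
brighter looks inverted for a drift correction; the formula is
implemented verbatim rather than "fixed", and condition-versus-control
fold changes are unaffected because the bead factor cancels. Decay fits
are ordinary least squares of `ln MFI` on day (≥3 distinct days, positive
MFIs); on noiseless exponential data the fit recovers `(I0, k)` to
machine precision.

## Problem sizes

The test suite and acceptance script run the screen at 1000 elements,
1000 cells per element, two replicates and 100,000 reads per sample;
end-to-end mapping demonstrations use 20,000–100,000 reads of 250 bp, and
alignment oracle checks use 200 random read/element pairs at ≤50/≤100 bp.
These sizes make every stage rerunnable on a laptop CPU in minutes while
keeping per-element counting noise (~100 reads per element in the pDNA
pool) at realistic screen levels.

## Known limitations

* The Welch test with n = 2 is intrinsically fragile; the undetermined
  path and the log-scale default mitigate but cannot repair it. A count
  model (negative binomial) is out of scope by design.
* The e-value proxy has no statistical calibration; use it only to order
  alignments of the same read.
* The silencing model is phenomenological. Its two rates are not
  identifiable from a single time point; the screen reads out their
  combined effect on day-15 gate occupancy.
* Shortlisted alignment assumes reads share a 16-mer with their source
  oligo; reads more divergent than ~6% substitutions may be dropped as
  unaligned rather than mismapped (they would fail the ≤3-mismatch filter
  anyway).
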