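# barrierscreen

Design and analysis of pooled **sort-seq screens for chromatin barrier
elements** — DNA sequences that block heterochromatin spreading into a
transgene and keep it expressed at repressive loci such as
lamina-associated domains (LADs).

In such a screen, a library of ~1000 candidate elements (CTCF-binding
sites ranked by predicted affinity, MIR retrotransposons, and random DNA
controls) is cloned next to an EGFP reporter, integrated at a
heterochromatic landing pad, and the cell pool is FACS-sorted by EGFP
level (Negative / Low / Medium / High) after two weeks of silencing.
Amplicon sequencing of each gate and of the plasmid pool (pDNA) turns
barrier activity into counts. `barrierscreen` implements every
computational stage of that workflow for people building or reanalyzing
such screens:

* **library_design** — quota-based selection (top/bottom affinity ranking,
  <5 kb LAD-boundary proximity), Esp3I-site exclusion, 250 bp centered
  cores with 50 bp cloning flanks, and coverage-planning arithmetic;
* **synthetic_screen** — a generative model of the screen (all-or-none
  silencing hazard plus graded intensity decay per element), FACS gating,
  and an amplicon-sequencing error model producing FASTQ with ground truth;
* **mapping** — linker/quality trimming, affine-gap Smith–Waterman against
  the library on both strands, best-alignment deduplication, and the
  post-alignment filters (≤3 mismatches, ≤3 gap columns, mapped length
  ≥ max possible − 10 nt);
* **enrichment** — percent abundance, fold change vs pDNA with a
  pseudocount, Welch t-tests across replicates,
  enriched/depleted/neutral calls at FC > 1.5 / FC < 0.67, p < 0.05,
  hit composition, replicate correlation, coverage and volcano/heatmap
  exports;
* **sequence_features** — GC content, overlapping degenerate-motif counts
  (USF E-box `CANNTG`, VEZF1 G-tract `GGGG`), position frequency matrices
  and information content in bits;
* **flow_kinetics** — bead-based day-to-day MFI normalization
  (`MFI × beads_dayn / beads_day1`), percent-EGFP⁺, and exponential decay
  fits `I(t) = I0·e^(−kt)` by least squares on log MFI.

The statistic at the core of hit calling is, per element *i* and sorted
population *g*:

    FC_ig = (mean_r A_igr + c) / (mean_r A_i,pDNA,r + c),

where `A` is percent abundance (100 × count / column total), `r` indexes
replicates and `c = 0.005` percentage points; significance is a two-tailed
unpaired Welch t-test across replicates (computed on log10(A + c) by
default), and an element is *enriched* iff FC > 1.5 and p < 0.05.

## Worked example

The `analysis/` directory is a numbered, self-documenting pipeline; each
script prints what it found and writes tables under `results/`:

```
python analysis/01_design_library.py      # library FASTA + manifest
python analysis/02_simulate_screen.py     # counts, ground truth, FASTQs
python analysis/03_map_reads.py           # trim/align/filter/count
python analysis/04_call_enrichment.py     # FC, p, hit calls, composition
python analysis/05_sequence_features.py   # GC, motifs, logos
python analysis/06_flow_kinetics.py       # bead adjust, decay fits
```

With the default seeds, step 01 prints

```
assembled library: 1000 elements (CTCF-High=450, CTCF-Low=50,
MIR-LAD_bound=30, MIR-random=420, RANDOM=50)
core length 250 bp, oligo length 300 bp
expected clones from 24 transfections at 0.4% integration: 57600 (57.6-fold library coverage)
```

i.e. the designed pool holds exactly the per-category quotas and the
planned transfection scheme covers the library >50-fold. Step 03 reports

```
noiseless: 20000 reads -> 20000 kept (100.00% assigned to the true element)
noiseless exact count recovery: True
noisy: 20000 reads -> 19996 kept (100.00% assigned to the true element)
```

— with sequencing errors switched off, mapping reproduces the simulated
counts *exactly*; with the full error model, 4 of 20,000 reads are lost to
the filters and none are misassigned. Step 04 then prints

```
pDNA library coverage: 98.5% of designed elements
Negative: 51 enriched elements
  dominant category: RANDOM (96%)
strong barriers recovered in High gate: 96%
null controls recovered in Negative gate: 98%
null false positives in High gate: 0%
```

reading: the plasmid pool covers 98.5% of designed elements; the
EGFP-negative gate is dominated by the inert random-sequence controls
(they silence fastest), while the strong barriers planted in the
simulation are recovered as enriched in the EGFP-high gate with no null
contamination.

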