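# Methods

## The placement problem

Small RNA-seq reads are 20–25 nt long and frequently have many equally
best-scoring alignment positions ("multi-mapping", MMAP, reads with
MMAP-value *n* = number of such positions), because siRNAs arise from
repetitive regions and identical mature miRNAs are encoded by paralogous
loci. The two common treatments — pick a position at random, or discard
MMAP reads — trade precision against sensitivity badly. `srnaplace`
implements local-context weighting: because small RNAs are processed out of
longer precursors, reads cluster at their true loci, so the local density
of *other* reads around each candidate position is evidence about which
position is the true origin.

## Placement model

All candidate positions for each read are enumerated first (exact-match,
both strands, capped at `max_sites` = 50 per read; the cap is
user-adjustable). The genome is divided into `bin_size` = 50 nt bins; an
alignment belongs to the bin of its leftmost aligned nucleotide regardless
of strand, with no pro-rating across boundaries. The *vicinity* of a
candidate site is the `window_bins` = 5 bin (~250 nt) window centered on
its bin, truncated at reference ends.

One pass over the complete all-alignment map accumulates two per-bin
tallies:

* **u** — number of alignments of uniquely aligned (*n* = 1) reads;
* **f** — fractional weight: every alignment contributes 1/*n* for its
  read, so each read distributes total weight 1 across its sites.

For a read with candidate sites *i* = 1..*n*, the placement probabilities
are

* **R** (random): p_i = 1/n — emulates default random placement;
* **U** (unique-weighting): p_i = u_i / Σ_j u_j, where u_i is the vicinity
  u-sum at site i;
* **F** (fractional): p_i = f_i / Σ_j f_j over vicinity f-sums;
* **N**: MMAP reads are not placed at all.

The read's own contributions are excluded from its vicinity sums before
normalisation: a read cannot be evidence for its own placement, and the
probabilities should reflect only its neighbours. The primary alignment is
then drawn from the categorical distribution p — placement is per read,
not per sequence, so 100 identical reads with probabilities (0.8, 0.2) are
expected to split ~80/20. All other candidate sites are written as
secondary SAM records (flag 0x100).

Degenerate cases: when every vicinity weight is equal — including all-zero
vicinities — the placement is a tie. Tied reads with
*n* > `tie_suppression_threshold` (default 3) are suppressed (emitted
unmapped); smaller ties are placed uniformly at random. Reads whose site
count exceeds `max_sites` are unmapped in every mode, with a distinct
status tag so they remain visible to retention and false-negative
accounting. Tie detection uses relative tolerance 1e-9, which is robust to
the accumulation order of the rational 1/n weights. Tallies are computed
once, before any placement; decisions never feed back into the tallies
(no EM-style iteration).

A zero U-mode denominator with nonzero f (a unique-free neighbourhood) is
a tie, not a fallback to F: the modes stay independent.

## Internal aligner

The internal aligner is exact-match (0 mismatches): every occurrence of
the read or its reverse complement on the plus strand of any reference is
a candidate site, reported at its leftmost plus-strand coordinate and
ordered (reference, pos, strand) for determinism, truncated
deterministically on overflow. Exactness is the simplest defensible
"best-match" semantics for 20–25 nt reads, and it means reads carrying a
simulated sequencing error are usually unalignable, supplying true
negatives to the evaluation. Mismatch-tolerant alignment is supported by
importing an externally produced all-alignment SAM (bowtie `-a` style)
instead. A naive brute-force scanner ships alongside the index as an
independent oracle for validation.

## Simulator

The simulator's defaults describe a plant-like sRNA-seq library:

* class mix 65% hc-siRNA / 30% miRNA / 5% tasiRNA (so a 5 M-read library
  holds ≈ 3.25 M / 1.5 M / 250 k reads);
* hc-siRNA: canonically 24 nt, loci 200–1000 nt (length uniform over the
  range), reads uniform over the locus on both strands;
* miRNA: canonically 21 nt from 125-nt hairpin loci; two registers on the
  plus strand — the mature miRNA at a fixed 5'-arm offset and the miRNA*
  duplex partner on the 3' arm with the canonical 2-nt 3' overhang — with
  a 10:1 mature:star abundance ratio (configurable);
* tasiRNA: canonically 21 nt from 140-nt loci in 21-nt phased registers
  anchored at the locus start on both strands (minus-strand registers
  offset by the 2-nt duplex overhang), register weights drawn log-normally
  once per locus;
* misprocessing: canonical length with probability 0.80, ±1 nt with 0.08
  each, ±2 nt with 0.02 each (lengths clamped to [20, 25]), and a ±1 nt 5'
  shift with total probability 0.10 — a dominant mode with minor variants;
* per-locus abundance log-normal(μ=0, σ=1): heavy-tailed expression;
* sequencing error: with probability 1e-4 per read, one substitution at a
  uniform position to a uniform alternative base (at most one error per
  read).

Within-locus abundance patterns of real libraries are not published in a
reusable form; the register/positional models above are explicit,
configurable stand-ins chosen to reproduce the qualitative archetypes
(dominant mature miRNA with a minor star; phased tasiRNA registers;
dispersed double-stranded hc-siRNA coverage).

Read IDs encode `locus|reference|start|strand|serial`, so truth is
recoverable from the FASTQ alone; the tab-separated truth table is the
canonical record.

### Repeat families

Multi-mapping is made controllable by planting repeat families: each
family is **one expressed hc-siRNA locus containing an identical core
segment** (`unit_length` nt, flanked by ≥ 75 nt of unique locus sequence),
plus `copy_number − 1` silent, base-identical copies of the core elsewhere
in the background. Reads wholly inside the core have MMAP-value exactly
`copy_number`; reads overlapping the flanks are unique and anchor the
vicinity weighting. This mirrors how repeat-derived siRNA loci behave in
real genomes, where most copies of a repeat are transcriptionally silent.
The design is deliberate: if entire loci were duplicated and all copies
expressed equally, no uniquely aligned read could exist near *any* copy,
every vicinity comparison would tie, and context-based placement would be
impossible in principle — an adversarial geometry rather than a realistic
one. Consequently the simulation is favourable terrain for U/F modes:
decoy vicinities are empty, so U-mode precision here is an upper bound on
what mixed real data (with partially expressed repeat copies and diverged
paralogs) would give. The directional conclusions (U ≫ R on MMAP
precision; U's F1 at least R's) are the transferable result, not the
absolute precision values.

The stock benchmark genome is one 1-Mb reference with 200 loci
(130 hc-siRNA / 60 miRNA / 10 tasiRNA); 30% of the hc-siRNA loci (39)
carry families with copy numbers uniform on 2–8 and core lengths uniform
on 100–250 nt. Cores ≤ 250 nt keep every core position within one window
of a unique flank, so suppression stays rare; loci and silent cores are
laid out with ≥ 250 nt gaps so vicinities do not bleed across items.
Background sequence is i.i.d. with GC = 0.37 (plant-like). At this scale a
100k-read library yields ~4–6k MMAP reads, enough for stable precision
estimates on one CPU in seconds; these sizes are the package's stock
configuration, chosen to keep the benchmark a desk-scale experiment.

What the simulator does **not** model: adapter remnants, quality-score
error profiles, ligation bias, RNA degradation, real-library abundance
spectra, diverged (non-identical) repeat copies, and overlapping loci.
Passing benchmarks here therefore demonstrate algorithmic correctness and
the qualitative precision/sensitivity trade-off, not absolute performance
on any particular real library.

## Evaluation

Each read is classified exactly once: **TP** placed at the true
(reference, strand, leftmost-coordinate) origin — exact match, no
positional tolerance, since simulated truth is exact; **FP** placed
anywhere else; **TN** unplaced with no valid alignment position; **FN**
unplaced despite at least one valid position (suppressed ties, overflow
reads and mode-N discards). Alignability for the TN/FN split is
recomputed under the same aligner settings used for placement, so an
error-bearing read that happens to align somewhere is scored honestly.

Precision = TP/(TP+FP), sensitivity = TP/(TP+FN), F1 their harmonic mean.
Two false-negative rates are emitted: `fnr_printed` = FN/(FP+TP), the form
printed in the method's original report, and the conventional
`fnr_conventional` = FN/(FN+TP); neither is silently substituted for the
other. Metrics with zero denominators are reported as missing, never 0.
Metrics can be stratified by MMAP-value (exact *n*, and cumulative
*n* ≤ cutoff); overflow reads have unknown exact *n* and are excluded from
the stratified rows. The retention curve reports the fraction of aligned
reads with *n* ≤ cutoff (overflow reads count in the denominator but are
never retained below the cap), and the strand-bias statistic is the ratio
of plus- to minus-strand primary records.

## Reproducibility

Every stochastic component takes an explicit seed; per-stage seeds in the
benchmark driver derive deterministically from one global seed. Identical
configuration plus seed reproduces byte-identical FASTA/FASTQ/TSV/SAM
outputs. The benchmark driver runs all placement modes against the same
all-alignment map, so mode comparisons are controlled for alignment.

## Known limitations

* Exact-match-only internal alignment; use external SAM import for
  mismatch tolerance.
* No gapped or quality-aware alignment, no color-space reads, no BAM
  output (SAM text only).
* No downstream locus clustering, hairpin annotation, or expression
  quantification; the placed SAM is the hand-off point.
* The prefix index holds all 20-mers of the genome in memory; genomes far
  beyond tens of Mb would need a different index.
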