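# srnaplace

Local-context weighted placement of multi-mapping small RNA-seq reads,
with a ground-truth read simulator and a benchmarking suite.

## The problem

Small RNA-seq reads (20–25 nt) frequently align equally well to many
genomic positions: endogenous siRNAs come from repetitive regions, and
identical mature miRNAs are encoded by paralogous loci. Libraries with
more than 50% multi-mapping (MMAP) reads are common. The usual treatments
are to pick one position at random (low precision — most choices are
wrong) or to discard MMAP reads (low sensitivity — half the library can
vanish). Neither is acceptable for locus annotation or quantification.

`srnaplace` places MMAP reads using their **local genomic context**. Small
RNAs are processed from longer precursors, so reads cluster at their true
loci; the density of *other* reads around each candidate position is
evidence for the true origin.

## The model

All best (exact-match) alignments of each read are enumerated first,
capped at `max_sites` = 50 per read. The genome is split into 50-nt bins
(an alignment belongs to the bin of its leftmost nucleotide) and the
*vicinity* of a candidate site is the five-bin (~250 nt) window centered
on its bin. One pass over the all-alignment map tallies, per bin, the
unique-read alignment count *u* and the fractional weight *f* (each
alignment contributes 1/*n* for its read with MMAP-value *n*). For a read
with sites *i* = 1..*n*:

| mode | probability of site *i* | behaviour |
|------|------------------------|-----------|
| R    | 1/*n*                  | random placement |
| U    | u_i / Σ_j u_j          | weight by nearby uniquely aligned reads |
| F    | f_i / Σ_j f_j          | weight by all nearby reads, 1/*n* each |
| N    | —                      | discard MMAP reads |

(vicinity sums exclude the read's own contributions). The primary
alignment is drawn from this distribution **per read** — identical
sequences can be placed at different positions — and all other candidates
are emitted as secondary SAM records. Ties across more than 3 positions
are suppressed (unmapped); reads exceeding the 50-site cap are unmapped in
every mode. Example: a two-site read with seven uniquely aligned reads
near one site and one near the other gets U-mode probabilities
(0.875, 0.125).

The simulator generates a synthetic genome with planted hc-siRNA, miRNA
and tasiRNA loci (65/30/5% of reads by default), exact-copy repeat cores
for controllable MMAP structure, misprocessing variants, and one
mis-sequenced base per 10,000 reads; every read is traceable to its true
origin, so placements can be scored as TP/FP/TN/FN with precision,
sensitivity, F1 and FNR. See `docs/methods.md` for the full model.

## Worked example

```python
from srnaplace import align, sim, evaluate
from srnaplace.place import PlacementConfig, place_library

gcfg = sim.SimGenomeConfig(reference_length=100_000, n_loci=20,
                           repeat_families=[(3, 180), (5, 200)], rng_seed=7)
sg = sim.generate_genome(gcfg)
lib = sim.simulate_library(sg.references, sg.loci,
                           sim.SimLibraryConfig(n_reads=10_000, rng_seed=8))
index = align.GenomeIndex(sg.references)
groups = align.align_library(zip(lib.read_ids, lib.sequences), index)
for mode in ("U", "R"):
    decisions = place_library(groups, PlacementConfig(mode=mode, rng_seed=9),
                              index.ref_lengths)
    per_read = evaluate.evaluate_library(decisions, lib.truth)
    print(f"mode {mode}:")
    print(evaluate.metrics_table(per_read)[
        ["scope", "tp", "fp", "tn", "fn", "precision", "sensitivity", "f1"]
    ].to_string(index=False))
```

prints

```
mode U:
    scope    tp  fp  tn  fn  precision  sensitivity  f1
      all 10000   0   0   0        1.0          1.0 1.0
mmap_only   123   0   0   0        1.0          1.0 1.0
mode R:
    scope   tp  fp  tn  fn  precision  sensitivity       f1
      all 9905  95   0   0   0.990500          1.0 0.995227
mmap_only   28  95   0   0   0.227642          1.0 0.370861
```

On this 100-kb toy genome, two repeat families (copy numbers 3 and 5)
create 123 multi-mapping reads. Unique-weighted placement (U) recovers
every one of their true origins, while random placement (R) is right only
23% of the time on the same reads — roughly the 1/copy-number rate you
would expect from guessing.

## Command line

```bash
srnaplace simulate  --reference-length 1000000 --n-loci 200 --n-reads 100000 \
                    --seed 1 --outdir simout
srnaplace align     --genome simout/genome.fa --reads simout/reads.fastq --out all.sam
srnaplace place     --in all.sam --out placed.sam --mode U --seed 2
srnaplace evaluate  --placed placed.sam --truth simout/truth.tsv \
                    --genome simout/genome.fa --outdir evalout
srnaplace benchmark --n-reads 100000 --seed 1 --outdir bench   # all four modes
```

External all-alignment SAM (e.g. `bowtie -a`) can be fed to `place`
directly, bypassing the internal exact-match aligner.

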