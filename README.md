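# trindex

A toolkit for **triple-indexed 16S rRNA V4 amplicon sequencing**: oligo and
plate design with the scheme's multiplexing arithmetic, demultiplexing of
paired reads on dual internal barcodes with heterogeneity spacers, a
branching-process PCR simulator that reproduces the main amplification
artifacts (per-cycle chimera formation, GC-dependent amplification bias), and
the benchmarking statistics used to evaluate such libraries on mock
communities.

## The problem

Highly multiplexed 16S amplicon studies face a cost/bias trade-off in how
sample identity is encoded. A two-step **dual-index** design puts both indices
on the second-stage (PCR2) primers, so multiplexing *n* samples needs index
sets with *i · j ≥ n* — the oligo count grows like 2√n. The **triple-index**
design modeled here instead places two 12-nt internal barcodes inside the PCR1
primers (read as part of the insert) and one 6-nt index on the PCR2 reverse
primer. A 96-well plate is covered by 12 forward × 8 reverse PCR1 barcode
combinations, and each extra plate costs exactly **one** additional oligo (its
PCR2 index):

```
N_triple(n) = 12 + 8 + 1 + ⌈n/96⌉        N_dual(n) = 2 + min{ i + j : i·j ≥ n }
```

so 1152 samples (12 plates) need 33 oligos versus 70 for dual indexing.
Each PCR1 primer is assembled 5′→3′ as

```
partial Illumina adapter · internal barcode (12 nt) · heterogeneity spacer (0–7 nt) · V4 priming (515fB/806rB)
```

The variable-length spacer frame-shifts the constant priming bases across
sequencing cycles, restoring the per-cycle base diversity that Illumina
cluster calling needs on low-complexity amplicon pools.

## What the package does

- **`trindex.oligo_design`** — assemble PCR1/PCR2 oligos from their parts,
  build 96-well layouts from barcode-set cartesian products (optionally
  excluding hairpin-prone identical-index pairs), compute the triple- vs
  dual-scheme oligo costs, and report per-cycle A/C/G/T composition of the
  read starts of a layout.
- **`trindex.demux`** — assign read pairs to samples by (pool index, forward
  barcode, reverse barcode), strip barcode/spacer/primer, merge mates over
  their 3′ overlap with quality-aware conflict resolution, and trim
  read-through reverse-primer tails. Assignment statistics satisfy an explicit
  conservation invariant (assigned + unassigned = input).
- **`trindex.pcr_sim`** — generate a 33-species mock community across a
  30–69 % GC gradient and amplify it as a branching process: each molecule
  duplicates per cycle with probability `e(GC) = e₀ − γ·max(0, GC − GC_ref)`,
  and each new copy becomes, with probability *q*, a chimera joining its
  prefix to another pool molecule's suffix at the homologous coordinate.
  Reads are emitted in the full triple-index layout with a per-read
  ground-truth table.
- **`trindex.benchmark`** — exact-identity read assignment (string equality on
  primer-trimmed fragments, both orientations), OTU tables, common scaling to
  the smallest library, rare-OTU filtering, deviation-from-expectation and
  abundance-vs-GC regression, chimera statistics, Bray–Curtis distance
  matrices (`d = 1 − 2Σmin/Σtotal`), PERMANOVA with adonis-style sequential
  sums of squares (`R² = SS_factor/SS_total` via the Gower-centered
  partition), and ANOSIM (`R = (r̄_between − r̄_within)/(M/2)`).

## Worked example

```python
import trindex as tx

cfg = tx.RunConfig(seed=7, n_samples=8, n_species=33, n_reads=2500,
                   pcr=tx.PcrParams(cycles1=25, cycles2=10, capacity=200_000),
                   template_amount=50_000)
report = tx.run_end_to_end(cfg)
print(report["otu_equals_truth"], report["mean_abs_deviation_pp"])
```

This simulates 8 samples × 2500 error-free, chimera-free read pairs of a
33-species mock community, demultiplexes them on the dual internal barcodes,
merges the mates and assigns the fragments by exact identity. It prints:

```
otu_equals_truth: True
total_pairs: 20000
assigned: {'S1': 2500, ..., 'S8': 2500}
merged: 20000
mean_abs_deviation_pp: 0.109
```

i.e. every one of the 20 000 pairs is assigned to its true sample, every pair
merges back to its source fragment, the OTU table equals the simulator's
ground-truth counts exactly, and the mean deviation of the estimated species
abundances from the 3 % equal-blending expectation is 0.11 percentage points
(pure multinomial sampling noise, since no bias mechanism was switched on).

The same pipeline is available from the shell:

```bash
trindex cost --samples 1152                  # -> 33 oligos (triple indexing)
trindex cost --samples 1152 --scheme dual    # -> 70 oligos
trindex simulate --samples 8 --reads 2500 --seed 7 --out sim/
trindex demux --r1 sim/i1_R1.fastq --r2 sim/i1_R2.fastq \
              --sheet sim/sample_sheet.tsv --out demux/
trindex bench --fragments demux/ --ref sim/reference.fasta --out report/
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults, the
numerical choices made, and known limitations.
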