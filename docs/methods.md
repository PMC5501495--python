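# Methods

## Scheme model

The library design encodes sample identity in three indices: two 12-nt
internal barcodes carried by the first-stage (PCR1) primers and sequenced as
part of the insert, plus a 6-nt index introduced by the second-stage (PCR2)
reverse primer and handled by the instrument's own index read. A PCR1 primer
is the 5′→3′ concatenation *partial adapter · barcode · heterogeneity spacer
(0–7 nt) · V4 priming sequence*; the priming sequences default to 515fB
(`GTGYCAGCMGCCGCGGTAA`) and 806rB (`GGACTACNVGGGTWTCTAAT`) and may contain
IUPAC degenerate codes. We take the read-start element order to be barcode
first, then spacer, then priming; because published renderings of this layout
are ambiguous, the parser also supports the spacer-before-barcode order
behind `DemuxConfig.barcode_before_spacer=False`.

The shipped primer table (`trindex/data/primers_default.tsv`) is **synthetic**:
12 forward and 8 reverse barcodes generated once with a fixed seed
(minimum pairwise Hamming distance 6 within each direction), spacer lengths
covering 0–7, and 12 TruSeq-style 6-nt PCR2 indices. The 8 reverse barcode
sequences deliberately reuse 8 of the forward index sequences, so the default
96-well plate contains exactly 8 same-index wells; the
`exclude_identical` layout option diverts those pairs (reason:
"identical-index hairpin risk"). Hairpin risk is modeled as the simple
predicate *forward sequence == reverse sequence*; no thermodynamic folding is
attempted. Larger plates or 384-well designs are supported only by supplying
larger barcode sets.

Oligo-cost arithmetic: `count_oligos_triple(n)` returns
`12 + 8 + 1 + ceil(n/96)` (PCR1 set sizes and plate size configurable);
`count_oligos_dual_alternative(n)` returns `2 + min{i + j : i·j ≥ n}`,
minimized exactly by scanning divisors up to √n (verified in tests against
exhaustive search).

## Demultiplexing

Barcodes are matched at the read start by nearest Hamming distance within a
mismatch budget (default 0). The budget must satisfy
`barcode_mismatch_max < d_min/2` for the barcode set's minimum pairwise
distance `d_min`; violating configurations are rejected at load time, which
guarantees unique decodability. The spacer length is taken from the barcode's
table entry (`lookup` mode, default) or scanned over 0–7 until the priming
sequence matches (`scan` mode). Priming is verified by IUPAC-aware matching
with a mismatch budget of `floor(0.1 · primer length)` — the 10 % tolerance is
the common adapter-trimming convention; the original pipelines do not state
their settings.

Mate merging reverse-complements read 2 and scores every overlap length from
`min(len1, len2)` down to `min_overlap` (default 10) by mismatch fraction,
keeping the lowest fraction (largest overlap on ties) if it is ≤ 0.25.
Disagreeing bases take the higher-quality call; agreeing bases keep the
higher quality. These defaults mirror widely used overlap-mergers. After
merging, a read-through reverse-priming site (the primer's reverse complement
at the 3′ end) is trimmed when present within the primer mismatch budget;
read-through *past* the reverse primer (into spacer/barcode) is not handled —
with the default 250-nt reads on 253-nt fragments reads do not reach it.

Reads shorter than the minimal construct count as `bad_fwd_barcode` /
`bad_rev_barcode`. The third (pool) index is taken from a per-file label or a
`pool=` token in read headers; instrument-level index-read demultiplexing is
deliberately out of scope. `DemuxStats` asserts conservation on every run:
assigned + unassigned = input pairs, and merged + merge-failed = assigned.

## PCR simulator

Amplification is a per-molecule branching process. Each cycle, a molecule of
GC fraction *g* duplicates with probability

```
e(g) = clamp(e0 − γ · max(0, g − g_ref) / b, 0, 1)
```

with defaults `e0 = 0.9`, `γ = 0` (no bias), `g_ref = 0.5`, and
`b = denaturation_boost = 1`. The penalty is piecewise-linear above `g_ref`:
the empirical observation behind it is an abundance-versus-GC slope, not an
efficiency law, so this law is the package's own construction and `γ` is a
free parameter, not a calibrated constant. `denaturation_boost > 1` shrinks
the penalty, emulating a longer melting step (10 s → 30 s) that rescues
high-GC templates.

Each new copy becomes a chimera with probability `q` (`chimera_prob`,
PCR1 cycles) or `chimera_prob2` (PCR2 cycles, default 0 — chimera formation
is dominated by the first-stage reaction on complex template). A chimera
joins the duplicating molecule's prefix, up to a breakpoint uniform over
interior positions, to the suffix of a partner molecule drawn proportionally
to pre-cycle copy numbers, at the homologous coordinate — a
template-switching mechanism that keeps fragment length constant. Provenance
records at most two parents: for chimeras of chimeras the recorded pair is
(first parent of the prefix donor, last parent of the suffix donor), an
approximation that affects only the rare q² events. Under this model the
chimeric fraction of the pool grows by roughly `q·e/(1+e)` per cycle, i.e.
approximately linearly in cycle number, which is the behaviour the
benchmarking statistics probe.

The tracked pool is capped at `capacity` molecules (default 2·10⁶) by
binomial thinning whenever a cycle overshoots it; the cumulative thinning
factor is recorded as `dilution`. Thinning keeps 35-cycle runs tractable and
adds a small extra variance to final proportions (repeated binomial
subsampling), which the statistical tests' tolerances account for.

Mock templates are random sequences of length 253 (V4-like) whose GC targets
are evenly spaced over 30–69 %, matching a community whose most extreme
member has 69 % GC; realized GC is within one base of target. Default input
is 2.5·10⁶ molecules per reaction split equally over 33 species (the
equal-blending expectation is 1/33 ≈ 3 % per species). Reads are emitted with
constant quality (Q40) and i.i.d. substitution errors only — Illumina error
profiles on this fragment are substitution-dominated, and indels would mostly
shift the overlap rather than change the statistics of interest. Degenerate
priming positions are realized uniformly per read. The same-index yield
collapse can be enabled in `simulate_experiment` as a fixed down-weighting
(default 10×) of read yield for wells whose two barcodes share a sequence.

### What the generator does and does not emulate

It emulates the *mechanisms* — GC-dependent competition, per-cycle chimera
formation, triple-index read layout, heterogeneity-spacer frame-shifting,
library-size variation — under controllable, seeded conditions with full
ground truth. It does not emulate polymerase error spectra, quality-score
decay, position-dependent error, indels, primer-template mismatch dynamics,
or real taxonomic sequence structure (templates are random, so exact-identity
assignment is cleanly decodable by construction). Passing tests therefore
demonstrate correctness of the pipeline's logic and the qualitative bias
behaviour, not quantitative agreement with any particular sequencing run.

## Benchmarking statistics

*Assignment* is exact string equality of the primer-trimmed merged fragment
against the reference, both orientations, via hash lookup — the "full-length
alignment at 100 % identity" criterion reduces to exactly this, with no
alignment heuristics to tune. *Common scaling* multiplies each library by
(smallest library size / own size), the expectation of infinitely repeated
rarefying; no rounding. *Rare-OTU filtering* drops OTUs with mean relative
abundance below 0.01 % and does not renormalize by default (a flag enables
it). *Deviation from expectation* is reported in percentage points — the mean
over species of |mean observed − expected| × 100 — the only reading
consistent with a 3 % per-species expectation.

*Bray–Curtis* uses `scipy.spatial.distance.pdist`; only symmetry, range and
zero diagonal are asserted (the index is semimetric). *PERMANOVA* partitions
the Gower-centered matrix `G = −½ J D² J`: the sum of squares of a nested
model with hat matrix `H` is `tr(HG)`, factors enter sequentially in the
user's column order (adonis behaviour; order is the user's responsibility and
is preserved in the report), and p-values come from label permutations of `G`
with the (x+1)/(n+1) correction. A single-level factor is degenerate but well
defined (SS = 0, R² = 0). *ANOSIM* mid-ranks all n(n−1)/2 distances and
reports `R = (r̄_between − r̄_within)/(M/2)` with a permutation p-value.
Default permutations: 10 000, seeded explicitly. The implementations are
validated in the test suite against explicit pairwise-sum oracles and
cross-checked against scikit-bio's one-way implementations.

## Problem sizes used in the shipped checks

The test suite runs entirely on generated data: the end-to-end recovery
check uses 8 samples × 2 500 error-free pairs (20 000 total); the chimera
linearity check uses a 3-cycle-level × 4-replicate factorial (12 samples,
q = 0.02, 50 000-molecule pools, 4 000 reads/sample); the GC-bias check
averages 20 seeded amplifications at γ = 0.4 and contrasts them with an
unbiased control of 5 000 reads judged against 4σ binomial bands. These sizes
give the stochastic assertions comfortable a-priori margins (verified by
pilot variance calculations) while keeping the whole suite under a minute.

## Known limitations

- The mapping from the simulator's `q` and `γ` to empirically reported
  per-cycle chimera slopes or abundance-per-GC slopes is not calibrated; the
  package makes no quantitative claims about real instruments.
- Chimera provenance is truncated to two parents (see above).
- The merger is exhaustive over overlap lengths (O(L²) per pair); it is fast
  enough for desk-scale data but is not a streaming HPC tool.
- Multi-factor PERMANOVA supports categorical factors only (no continuous
  covariates or interactions).
- Barcode matching assumes fixed-length, indel-free barcodes; an indel in the
  first 12 nt of a read shifts everything downstream and the pair is counted
  unassigned.
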