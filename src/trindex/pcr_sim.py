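"""Branching-process PCR simulator with GC-dependent efficiency and chimeras.

The generator produces the kind of data the triple-index scheme is
benchmarked on: a mock community of V4-length templates spanning a GC
gradient, amplified by a per-molecule branching process in which

* each molecule duplicates each cycle with probability
  ``e(GC) = clamp(e0 - gamma * max(0, GC - gc_ref) / boost, 0, 1)`` — high-GC
  templates denature less completely and are progressively out-competed;
* each new copy is, with probability ``q``, a chimera: the prefix of its
  template up to a uniform interior breakpoint joined to the suffix of
  another pool molecule at the homologous coordinate (template switching),
  so the chimera burden of the pool grows roughly linearly in cycle number;
* the tracked pool is capped at ``capacity`` molecules by uniform thinning
  (recorded as a dilution factor), since a branching process at 35 cycles
  would otherwise explode.

Reads are then drawn from the final pool in the full triple-index layout
(barcode + heterogeneity spacer + degenerate priming + fragment, mate
reverse-complemented) with i.i.d. substitution errors, alongside a per-read
ground-truth table used by the benchmarking statistics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .demux import SampleSheet
from .oligo_design import (
    IUPAC_CODES,
    BarcodeEntry,
    SchemeSpec,
    gc_fraction,
    reverse_complement,
)

DEFAULT_READ_LEN = 250
DEFAULT_QUALITY_CHAR = "I"  # constant Q40; error model is substitution-only

# Mock community defaults: 33 species blended to equal proportions across a
# 30-69% GC gradient, 2.5e6 input molecules per reaction.
DEFAULT_N_SPECIES = 33
DEFAULT_FRAGMENT_LEN = 253
DEFAULT_GC_RANGE = (0.30, 0.69)
DEFAULT_INPUT_MOLECULES = 2_500_000


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Template:
    species_id: str
    sequence: str
    gc: float

    def __post_init__(self) -> None:
        realized = gc_fraction(self.sequence)
        if abs(realized - self.gc) * len(self.sequence) > 1.0 + 1e-9:
            raise ValueError(
                f"{self.species_id}: stored GC {self.gc:.4f} differs from computed "
                f"{realized:.4f} by more than one base"
            )


@dataclass
class TemplateSet:
    """Mock-community templates with a per-template starting copy number."""

    templates: list[Template]
    initial_copies: int

    def __post_init__(self) -> None:
        ids = [t.species_id for t in self.templates]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids")
        seqs = [t.sequence for t in self.templates]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate template sequences")
        if self.initial_copies < 1:
            raise ValueError("initial_copies must be >= 1")

    def __len__(self) -> int:
        return len(self.templates)

    def expected_proportions(self) -> pd.Series:
        """Equal-blending expectation: 1/n per species."""
        n = len(self.templates)
        return pd.Series(1.0 / n, index=[t.species_id for t in self.templates])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.templates:
                fh.write(f">{t.species_id} gc={t.gc:.4f}\n{t.sequence}\n")


def make_mock_templates(
    n_species: int = DEFAULT_N_SPECIES,
    length: int = DEFAULT_FRAGMENT_LEN,
    gc_min: float = DEFAULT_GC_RANGE[0],
    gc_max: float = DEFAULT_GC_RANGE[1],
    seed: int | np.random.Generator | None = 0,
    initial_copies: int = DEFAULT_INPUT_MOLECULES // DEFAULT_N_SPECIES,
) -> TemplateSet:
    """Generate a mock community with GC targets evenly spaced on [gc_min, gc_max].

    Each template is a random sequence whose realized GC count is the target
    rounded to the nearest base, so realized GC is within one base of target.
    Deterministic for a given seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if not 0.0 <= gc_min <= gc_max <= 1.0:
        raise ValueError("require 0 <= gc_min <= gc_max <= 1")
    if length < 20:
        raise ValueError("length too short for a V4-like fragment")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    targets = np.linspace(gc_min, gc_max, n_species)
    templates: list[Template] = []
    seen: set[str] = set()
    for i, gc in enumerate(targets):
        while True:
            n_gc = int(round(gc * length))
            bases = np.empty(length, dtype="<U1")
            gc_pos = rng.permutation(length)[:n_gc]
            at_mask = np.ones(length, dtype=bool)
            at_mask[gc_pos] = False
            bases[gc_pos] = rng.choice(["G", "C"], size=n_gc)
            bases[at_mask] = rng.choice(["A", "T"], size=length - n_gc)
            seq = "".join(bases)
            if seq not in seen:
                seen.add(seq)
                break
        templates.append(Template(f"sp{i + 1:02d}", seq, n_gc / length))
    return TemplateSet(templates=templates, initial_copies=initial_copies)


def load_reference_fasta_templates(path, initial_copies: int = 1) -> TemplateSet:
    """Read templates from FASTA (e.g. a real mock-community reference)."""
    from Bio import SeqIO

    templates = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        templates.append(Template(rec.id, seq, gc_fraction(seq)))
    return TemplateSet(templates=templates, initial_copies=initial_copies)


# ---------------------------------------------------------------------------
# PCR branching process
# ---------------------------------------------------------------------------

@dataclass
class PcrParams:
    """Two-stage PCR settings.

    ``chimera_prob`` applies to PCR1 cycles; PCR2 uses ``chimera_prob2``
    (default 0 — chimera formation is dominated by the first-stage reaction).
    ``denaturation_boost`` >= 1 shrinks the GC penalty, modeling a longer
    melting step that rescues high-GC templates.
    """

    cycles1: int = 30
    cycles2: int = 10
    base_efficiency: float = 0.9
    gc_penalty: float = 0.0
    gc_ref: float = 0.5
    chimera_prob: float = 0.0
    chimera_prob2: float = 0.0
    capacity: int = 2_000_000
    denaturation_boost: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.base_efficiency <= 1.0:
            raise ValueError("base_efficiency must be in (0, 1]")
        for name in ("chimera_prob", "chimera_prob2"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.denaturation_boost < 1.0:
            raise ValueError("denaturation_boost must be >= 1")
        if min(self.cycles1, self.cycles2) < 0:
            raise ValueError("cycle counts must be >= 0")


def amplification_efficiency(gc: float, p: PcrParams) -> float:
    """Per-cycle duplication probability for a molecule of the given GC fraction.

    Piecewise linear: ``e0`` below ``gc_ref``, penalized by
    ``gamma * (gc - gc_ref) / denaturation_boost`` above it, clamped to [0, 1].
    Monotone non-increasing in GC.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    e = p.base_efficiency - p.gc_penalty * max(0.0, gc - p.gc_ref) / p.denaturation_boost
    return min(1.0, max(0.0, e))


@dataclass(frozen=True)
class Molecule:
    """A distinct amplicon genotype with provenance.

    ``parents`` holds one species id for faithful copies and two (prefix
    donor, suffix donor) for chimeras; ``breakpoint`` is set iff chimeric.
    """

    sequence: str
    parents: tuple[str, ...]
    is_chimera: bool
    breakpoint: int | None
    born_cycle: int

    def __post_init__(self) -> None:
        if self.is_chimera != (len(self.parents) == 2) or self.is_chimera != (
            self.breakpoint is not None
        ):
            raise ValueError("chimera flag, parent count and breakpoint are inconsistent")


@dataclass
class MoleculePool:
    """Final PCR pool: distinct genotypes with copy numbers."""

    molecules: list[Molecule]
    counts: np.ndarray  # int64, parallel to molecules
    dilution: float = 1.0  # cumulative capacity-thinning factor applied

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def chimera_fraction(self) -> float:
        if self.total == 0:
            return 0.0
        mask = np.fromiter((m.is_chimera for m in self.molecules), dtype=bool,
                           count=len(self.molecules))
        return float(self.counts[mask].sum() / self.total)

    def species_counts(self) -> pd.Series:
        """Copy number per non-chimeric parent species."""
        out: dict[str, int] = {}
        for m, c in zip(self.molecules, self.counts):
            if not m.is_chimera:
                out[m.parents[0]] = out.get(m.parents[0], 0) + int(c)
        return pd.Series(out, dtype="int64")


def simulate_pcr(
    template_set: TemplateSet,
    params: PcrParams,
    seed: int | np.random.Generator | None = 0,
    initial_copies: int | None = None,
) -> MoleculePool:
    """Run the two-stage branching-process amplification.

    Each cycle, every molecule duplicates independently with probability
    ``e(GC)``; each new copy becomes a chimera with the stage's chimera
    probability, joining its own prefix to the homologous suffix of a pool
    molecule drawn proportionally to pre-cycle copy numbers.  The pool is
    thinned uniformly whenever it exceeds ``capacity``.
    """
    if not template_set.templates:
        raise ValueError("empty template set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n0 = initial_copies if initial_copies is not None else template_set.initial_copies

    molecules: list[Molecule] = [
        Molecule(t.sequence, (t.species_id,), False, None, 0) for t in template_set.templates
    ]
    counts = np.full(len(molecules), n0, dtype=np.int64)
    eff = np.array(
        [amplification_efficiency(gc_fraction(m.sequence), params) for m in molecules]
    )
    dilution = 1.0

    total_cycles = params.cycles1 + params.cycles2
    for cycle in range(1, total_cycles + 1):
        q = params.chimera_prob if cycle <= params.cycles1 else params.chimera_prob2
        pre_counts = counts.copy()
        pre_total = int(pre_counts.sum())
        if pre_total == 0:
            break
        dups = rng.binomial(counts, eff)
        n_chim = rng.binomial(dups, q) if q > 0 else np.zeros_like(dups)
        counts = counts + dups - n_chim

        n_new = int(n_chim.sum())
        if n_new:
            prefix_idx = np.repeat(np.arange(len(molecules)), n_chim)
            partner_idx = rng.choice(
                len(pre_counts), size=n_new, p=pre_counts / pre_total
            )
            new_mols: list[Molecule] = []
            new_eff: list[float] = []
            for i, j in zip(prefix_idx, partner_idx):
                a, b = molecules[i], molecules[j]
                L = min(len(a.sequence), len(b.sequence))
                bp = int(rng.integers(1, L))
                seq = a.sequence[:bp] + b.sequence[bp:]
                chim = Molecule(
                    sequence=seq,
                    parents=(a.parents[0], b.parents[-1]),
                    is_chimera=True,
                    breakpoint=bp,
                    born_cycle=cycle,
                )
                new_mols.append(chim)
                new_eff.append(amplification_efficiency(gc_fraction(seq), params))
            molecules.extend(new_mols)
            counts = np.concatenate([counts, np.ones(n_new, dtype=np.int64)])
            eff = np.concatenate([eff, np.array(new_eff)])

        total = int(counts.sum())
        if total > params.capacity:
            keep = params.capacity / total
            counts = rng.binomial(counts, keep)
            dilution *= keep
            alive = counts > 0
            if not alive.all():
                molecules = [m for m, a in zip(molecules, alive) if a]
                counts = counts[alive]
                eff = eff[alive]

    return MoleculePool(molecules=molecules, counts=counts, dilution=dilution)


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WellAssignment:
    """The library-layout coordinates of one sample."""

    pool_index: str
    fwd: BarcodeEntry
    rev: BarcodeEntry


TRUTH_COLUMNS = [
    "read_id", "sample_id", "parents", "is_chimera", "breakpoint", "born_cycle",
    "fwd_barcode", "rev_barcode", "fwd_spacer_len", "rev_spacer_len",
]


def _realize_iupac(seq: str, rng: np.random.Generator) -> str:
    """Replace degenerate codes by a concrete base drawn uniformly."""
    if set(seq) <= set("ACGT"):
        return seq
    out = []
    for c in seq:
        exp = IUPAC_CODES[c]
        if len(exp) == 1:
            out.append(c)
        else:
            choices = sorted(exp)
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _add_errors(seq: str, err_rate: float, rng: np.random.Generator) -> str:
    if err_rate <= 0.0 or not seq:
        return seq
    n_err = rng.binomial(len(seq), err_rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    arr = list(seq)
    for p in pos:
        alternatives = [b for b in "ACGT" if b != arr[p]]
        arr[p] = alternatives[rng.integers(3)]
    return "".join(arr)


def sample_reads(
    pool: MoleculePool,
    n_reads: int,
    well: WellAssignment,
    scheme: SchemeSpec,
    sample_id: str,
    read_len: int = DEFAULT_READ_LEN,
    err_rate: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> tuple[list[tuple[str, str, str, str, str]], pd.DataFrame]:
    """Draw reads from the pool and emit full-layout paired reads plus truth.

    Molecules are drawn with replacement proportionally to copy number.  The
    amplicon construct is ``fwd_barcode + fwd_spacer + fwd_priming + fragment
    + rc(rev_priming) + rc(rev_spacer) + rc(rev_barcode)``; read 1 is its
    first ``read_len`` bases and read 2 the first ``read_len`` bases of its
    reverse complement.  Degenerate priming positions are realized per read;
    substitution errors are i.i.d. at ``err_rate``.

    Returns ``(reads, truth)`` where each read is
    ``(title, r1_seq, r1_qual, r2_seq, r2_qual)`` and the FASTQ title carries
    a ``pool=`` token for downstream pool resolution.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reads: list[tuple[str, str, str, str, str]] = []
    truth_rows: list[tuple] = []
    if n_reads == 0:
        return reads, pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    if pool.total == 0:
        raise ValueError("cannot sample reads from an empty pool")

    probs = pool.counts / pool.total
    idx = rng.choice(len(pool.counts), size=n_reads, p=probs)
    fwd, rev = well.fwd, well.rev
    for k, i in enumerate(idx):
        mol = pool.molecules[i]
        pf = _realize_iupac(scheme.parts.priming_fwd, rng)
        pr = _realize_iupac(scheme.parts.priming_rev, rng)
        construct = (
            fwd.sequence + fwd.spacer + pf + mol.sequence
            + reverse_complement(pr) + reverse_complement(rev.spacer)
            + reverse_complement(rev.sequence)
        )
        if read_len > len(construct):
            raise ValueError(
                f"read_len {read_len} exceeds construct length {len(construct)}"
            )
        r1 = _add_errors(construct[:read_len], err_rate, rng)
        r2 = _add_errors(reverse_complement(construct)[:read_len], err_rate, rng)
        rid = f"{sample_id}.{k + 1}"
        title = f"{rid} pool={well.pool_index}"
        qual = DEFAULT_QUALITY_CHAR * read_len
        reads.append((title, r1, qual, r2, qual))
        truth_rows.append((
            rid, sample_id, "+".join(mol.parents), mol.is_chimera,
            mol.breakpoint if mol.breakpoint is not None else -1, mol.born_cycle,
            fwd.name, rev.name, len(fwd.spacer), len(rev.spacer),
        ))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth


# ---------------------------------------------------------------------------
# Experiment-level driver
# ---------------------------------------------------------------------------

@dataclass
class SampleSpec:
    """One row of a simulated experiment design (factorial or otherwise)."""

    sample_id: str
    pool_index: str
    fwd_barcode: str
    rev_barcode: str
    params: PcrParams = field(default_factory=PcrParams)
    template_amount: int = DEFAULT_INPUT_MOLECULES
    n_reads: int = 20_000
    read_len: int = DEFAULT_READ_LEN
    err_rate: float = 0.0


@dataclass
class ExperimentBundle:
    """In-memory result of :func:`simulate_experiment`."""

    reads_by_pool: dict[str, list[tuple[str, str, str, str, str]]]
    truth: pd.DataFrame
    manifest: pd.DataFrame
    sheet: SampleSheet
    pools: dict[str, MoleculePool]  # per-sample final pools, keyed by sample id


def simulate_experiment(
    design: Sequence[SampleSpec],
    scheme: SchemeSpec,
    template_set: TemplateSet,
    seed: int = 0,
    out_dir=None,
    same_index_yield_penalty: float = 1.0,
) -> ExperimentBundle:
    """Simulate one library per design row and pool reads by PCR2 index.

    Each sample gets an independent child seed of ``seed``, one PCR run and
    one read draw.  ``same_index_yield_penalty`` > 1 down-weights the read
    yield of wells whose forward and reverse barcode sequences are identical
    (the same-index yield collapse), dividing ``n_reads`` by the penalty.

    With ``out_dir`` set, writes per-pool paired FASTQ, a ground-truth TSV, a
    manifest TSV and the sample sheet.
    """
    ids = [s.sample_id for s in design]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in design")
    seen_wells = set()
    for s in design:
        key = (s.pool_index, s.fwd_barcode, s.rev_barcode)
        if key in seen_wells:
            raise ValueError(f"well {key} assigned to more than one sample")
        seen_wells.add(key)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(design))

    reads_by_pool: dict[str, list] = {}
    truth_frames: list[pd.DataFrame] = []
    manifest_rows: list[dict] = []
    pools: dict[str, MoleculePool] = {}
    sheet_rows: list[tuple[str, str, str, str]] = []

    n_species = len(template_set)
    for spec, child in zip(design, children):
        rng = np.random.default_rng(child)
        fwd = scheme.barcodes[spec.fwd_barcode]
        rev = scheme.barcodes[spec.rev_barcode]
        well = WellAssignment(spec.pool_index, fwd, rev)
        per_template = max(1, round(spec.template_amount / n_species))
        pool = simulate_pcr(template_set, spec.params, seed=rng,
                            initial_copies=per_template)
        n_reads = spec.n_reads
        if same_index_yield_penalty > 1.0 and fwd.sequence == rev.sequence:
            n_reads = max(1, round(n_reads / same_index_yield_penalty))
        reads, truth = sample_reads(
            pool, n_reads, well, scheme, spec.sample_id,
            read_len=spec.read_len, err_rate=spec.err_rate, seed=rng,
        )
        pools[spec.sample_id] = pool
        reads_by_pool.setdefault(spec.pool_index, []).extend(reads)
        truth_frames.append(truth)
        sheet_rows.append((spec.pool_index, spec.fwd_barcode, spec.rev_barcode,
                           spec.sample_id))
        manifest_rows.append({
            "sample_id": spec.sample_id,
            "pool_index": spec.pool_index,
            "fwd_barcode": spec.fwd_barcode,
            "rev_barcode": spec.rev_barcode,
            "cycles1": spec.params.cycles1,
            "cycles2": spec.params.cycles2,
            "template_amount": spec.template_amount,
            "n_reads": n_reads,
        })

    truth = (
        pd.concat(truth_frames, ignore_index=True)
        if truth_frames else pd.DataFrame(columns=TRUTH_COLUMNS)
    )
    manifest = pd.DataFrame(manifest_rows)
    bundle = ExperimentBundle(
        reads_by_pool=reads_by_pool,
        truth=truth,
        manifest=manifest,
        sheet=SampleSheet(sheet_rows),
        pools=pools,
    )
    if out_dir is not None:
        write_experiment(bundle, out_dir)
    return bundle


def write_experiment(bundle: ExperimentBundle, out_dir) -> None:
    """Write pooled paired FASTQ, truth table, manifest and sample sheet."""
    os.makedirs(out_dir, exist_ok=True)
    for pool_index, reads in bundle.reads_by_pool.items():
        with open(os.path.join(out_dir, f"{pool_index}_R1.fastq"), "w") as h1, \
                open(os.path.join(out_dir, f"{pool_index}_R2.fastq"), "w") as h2:
            for title, s1, q1, s2, q2 in reads:
                h1.write(f"@{title}\n{s1}\n+\n{q1}\n")
                h2.write(f"@{title}\n{s2}\n+\n{q2}\n")
    bundle.truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    bundle.manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    bundle.sheet.to_file(os.path.join(out_dir, "sample_sheet.tsv"))


def factorial_design(
    layout_wells: Sequence[tuple[str, str, str]],
    cycles1_levels: Sequence[int] = (25, 30, 35),
    template_levels: Sequence[int] = (DEFAULT_INPUT_MOLECULES,),
    replicates: int = 1,
    base_params: PcrParams | None = None,
    n_reads: int = 20_000,
    err_rate: float = 0.0,
    read_len: int = DEFAULT_READ_LEN,
) -> list[SampleSpec]:
    """Cross cycles1 x template-amount levels over a list of wells.

    ``layout_wells`` supplies (pool_index, fwd, rev) triples in assignment
    order; the design consumes one well per sample and errors out if it runs
    short.  Mirrors the factorial structure used to probe cycle/template
    effects.
    """
    base = base_params or PcrParams()
    design: list[SampleSpec] = []
    k = 0
    for c1 in cycles1_levels:
        for amount in template_levels:
            for r in range(replicates):
                if k >= len(layout_wells):
                    raise ValueError("not enough wells for the requested design")
                pool_index, fwd, rev = layout_wells[k]
                k += 1
                design.append(SampleSpec(
                    sample_id=f"c{c1}_t{amount}_r{r + 1}",
                    pool_index=pool_index,
                    fwd_barcode=fwd,
                    rev_barcode=rev,
                    params=replace(base, cycles1=c1),
                    template_amount=amount,
                    n_reads=n_reads,
                    err_rate=err_rate,
                    read_len=read_len,
                ))
    return design
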