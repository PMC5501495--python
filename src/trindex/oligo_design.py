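"""Triple-index oligo assembly, plate layout and multiplexing arithmetic.

The library-preparation scheme modeled here encodes sample identity in three
indices: a 12-nt internal barcode on the forward PCR1 primer, a 12-nt internal
barcode on the reverse PCR1 primer, and a 6-nt index introduced by the PCR2
reverse primer.  PCR1 primers are built from four parts (5'->3'):

    partial Illumina adapter | internal barcode | heterogeneity spacer (0-7 nt)
    | V4 priming sequence (515fB / 806rB, IUPAC-degenerate)

The variable-length heterogeneity spacer frame-shifts the constant priming
bases across sequencing cycles so that per-cycle base composition stays
diverse, which low-complexity amplicon libraries otherwise lack.

This module assembles those oligos, lays out 96-well plates from the cartesian
product of forward x reverse barcode sets, computes the oligo cost of the
triple-index scheme versus a conventional two-step dual-index scheme, and
reports per-cycle base composition diagnostics for a layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

DNA_BASES = frozenset("ACGT")

#: IUPAC nucleotide codes -> the set of concrete bases each stands for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

MAX_SPACER_LEN = 7
DEFAULT_PLATE_SIZE = 96

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC fraction of a plain-DNA string."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarcodeEntry:
    """One internal barcode: 12-nt index plus its paired heterogeneity spacer."""

    name: str
    sequence: str
    spacer: str
    direction: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"unknown barcode direction {self.direction!r}")
        if not set(self.sequence) <= DNA_BASES:
            raise ValueError(f"barcode {self.name}: non-ACGT base in {self.sequence!r}")
        if not set(self.spacer) <= DNA_BASES:
            raise ValueError(f"barcode {self.name}: non-ACGT base in spacer")
        if not 0 <= len(self.spacer) <= MAX_SPACER_LEN:
            raise ValueError(
                f"barcode {self.name}: spacer length {len(self.spacer)} outside [0, {MAX_SPACER_LEN}]"
            )


class BarcodeSet:
    """A validated collection of internal barcodes.

    Invariants enforced at construction: unique names, all sequences the same
    length within a direction, spacer lengths in [0, 7], ACGT alphabet.
    """

    def __init__(self, entries: Iterable[BarcodeEntry]):
        self.entries: list[BarcodeEntry] = list(entries)
        if not self.entries:
            raise ValueError("empty barcode set")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate barcode names")
        for direction in ("forward", "reverse"):
            lens = {len(e.sequence) for e in self.entries if e.direction == direction}
            if len(lens) > 1:
                raise ValueError(f"{direction} barcodes have mixed lengths {sorted(lens)}")
        self._by_name = {e.name: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> BarcodeEntry:
        return self._by_name[name]

    def subset(self, direction: str) -> "BarcodeSet":
        sub = [e for e in self.entries if e.direction == direction]
        return BarcodeSet(sub)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def barcode_length(self, direction: str) -> int:
        lens = {len(e.sequence) for e in self.entries if e.direction == direction}
        if not lens:
            raise ValueError(f"no {direction} barcodes in set")
        return lens.pop()

    def min_pairwise_hamming(self) -> int:
        """Smallest pairwise Hamming distance among barcodes in this set.

        The decodability bound for mismatch-tolerant demultiplexing: a set can
        absorb up to floor((d_min - 1) / 2) substitutions unambiguously.
        """
        seqs = [e.sequence for e in self.entries]
        if len(seqs) < 2:
            return len(seqs[0])
        return min(
            hamming(a, b) for i, a in enumerate(seqs) for b in seqs[i + 1:]
        )


@dataclass(frozen=True)
class PrimerParts:
    """The constant parts of the two-step primer system.

    ``priming_fwd`` / ``priming_rev`` are the V4 priming sequences (515fB and
    806rB by default) and may contain IUPAC degenerate codes; all adapter
    parts are plain DNA.  ``pcr2_indices`` are the 6-nt third indices carried
    by the PCR2 reverse primers (one per pooled plate).
    """

    partial_adapter_fwd: str
    partial_adapter_rev: str
    priming_fwd: str
    priming_rev: str
    pcr2_adapter_fwd: str
    pcr2_adapter_rev: str
    pcr2_indices: tuple[str, ...]

    def __post_init__(self) -> None:
        for label, seq in (("priming_fwd", self.priming_fwd), ("priming_rev", self.priming_rev)):
            if not seq:
                raise ValueError(f"{label} is empty")
            bad = set(seq) - set(IUPAC_CODES)
            if bad:
                raise ValueError(f"{label} contains non-IUPAC characters {sorted(bad)}")
        for idx in self.pcr2_indices:
            if len(idx) != 6 or not set(idx) <= DNA_BASES:
                raise ValueError(f"PCR2 index {idx!r} is not a 6-nt ACGT string")


@dataclass
class SchemeSpec:
    """A complete triple-index scheme: constant parts plus barcode sets."""

    parts: PrimerParts
    barcodes: BarcodeSet

    @property
    def forward(self) -> BarcodeSet:
        return self.barcodes.subset("forward")

    @property
    def reverse(self) -> BarcodeSet:
        return self.barcodes.subset("reverse")

    def read_start_construct(self, barcode: BarcodeEntry) -> str:
        """Sequence at the start of a read from this well side: barcode+spacer+priming."""
        priming = (
            self.parts.priming_fwd if barcode.direction == "forward" else self.parts.priming_rev
        )
        return barcode.sequence + barcode.spacer + priming


@dataclass(frozen=True)
class Well:
    well_id: str
    fwd: str  # forward barcode name
    rev: str  # reverse barcode name


@dataclass
class PlateLayout:
    """Up to 96 wells assigned (fwd, rev) barcode pairs, plus one pool index."""

    wells: list[Well]
    pool_index: str
    excluded: list[tuple[str, str, str]] = field(default_factory=list)  # (fwd, rev, reason)

    def __post_init__(self) -> None:
        pairs = [(w.fwd, w.rev) for w in self.wells]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (fwd, rev) pair in plate layout")

    def __len__(self) -> int:
        return len(self.wells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(w.well_id, w.fwd, w.rev, self.pool_index) for w in self.wells],
            columns=["well", "fwd_barcode", "rev_barcode", "pool_index"],
        )


@dataclass
class SchemeCost:
    """Oligo count for multiplexing ``n_samples``, with a per-role breakdown."""

    n_samples: int
    plate_size: int
    breakdown: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.breakdown.values()):
            raise ValueError("negative count in cost breakdown")

    @property
    def n_oligos(self) -> int:
        return sum(self.breakdown.values())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def assemble_pcr1_primer(
    parts: PrimerParts, barcode: BarcodeEntry, direction: str | None = None
) -> str:
    """Assemble a full PCR1 oligo (5'->3'): adapter + barcode + spacer + priming.

    ``direction`` may be given to assert the barcode is of the expected
    orientation; a mismatch raises ``ValueError``.
    """
    if direction is not None and direction != barcode.direction:
        raise ValueError(
            f"barcode {barcode.name} is {barcode.direction}, requested {direction}"
        )
    if barcode.direction == "forward":
        adapter, priming = parts.partial_adapter_fwd, parts.priming_fwd
    else:
        adapter, priming = parts.partial_adapter_rev, parts.priming_rev
    return adapter + barcode.sequence + barcode.spacer + priming


def _well_ids(n: int, plate_size: int) -> list[str]:
    """Row-major A1..H12 well ids (extended alphabetically past one plate)."""
    n_cols = 12 if plate_size % 8 == 0 else plate_size
    ids = []
    for i in range(n):
        row, col = divmod(i, n_cols)
        ids.append(f"{chr(ord('A') + row)}{col + 1}")
    return ids


def build_plate_layout(
    fwd: BarcodeSet,
    rev: BarcodeSet,
    exclude_identical: bool = False,
    plate_size: int = DEFAULT_PLATE_SIZE,
    pool_index: str = "i1",
) -> PlateLayout:
    """Lay out a plate from the cartesian product of forward x reverse barcodes.

    Pairs are enumerated forward-major in set order, truncated to
    ``plate_size`` wells.  With ``exclude_identical`` the pairs whose two
    barcode sequences are identical (a hairpin-prone construct, the scheme's
    same-index wells) are diverted to ``excluded`` before truncation.
    """
    fwd_entries = [e for e in fwd if e.direction == "forward"]
    rev_entries = [e for e in rev if e.direction == "reverse"]
    if not fwd_entries or not rev_entries:
        raise ValueError("both forward and reverse barcode sets must be non-empty")

    kept: list[tuple[str, str]] = []
    excluded: list[tuple[str, str, str]] = []
    for f in fwd_entries:
        for r in rev_entries:
            if exclude_identical and f.sequence == r.sequence:
                excluded.append((f.name, r.name, "identical-index hairpin risk"))
            else:
                kept.append((f.name, r.name))
    kept = kept[:plate_size]
    ids = _well_ids(len(kept), plate_size)
    wells = [Well(w, f, r) for w, (f, r) in zip(ids, kept)]
    return PlateLayout(wells=wells, pool_index=pool_index, excluded=excluded)


def count_oligos_triple(
    n_samples: int,
    plate_size: int = DEFAULT_PLATE_SIZE,
    n_pcr1_fwd: int = 12,
    n_pcr1_rev: int = 8,
    n_pcr2_indices: int | None = None,
) -> SchemeCost:
    """Oligo cost of the triple-index scheme.

    One plate of ``plate_size`` samples consumes the fixed PCR1 sets (default
    12 forward + 8 reverse) plus the single universal PCR2 forward primer;
    each additional plate only adds one indexed PCR2 reverse primer, so cost
    grows by one oligo per ``plate_size`` samples.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_pcr1_fwd * n_pcr1_rev < plate_size:
        raise ValueError(
            f"{n_pcr1_fwd} x {n_pcr1_rev} PCR1 combinations cannot fill a "
            f"{plate_size}-well plate"
        )
    n_plates = math.ceil(n_samples / plate_size)
    if n_pcr2_indices is not None and n_plates > n_pcr2_indices:
        shortfall = n_samples - plate_size * n_pcr2_indices
        raise ValueError(
            f"{n_samples} samples need {n_plates} PCR2 indices but only "
            f"{n_pcr2_indices} are available (shortfall: {shortfall} samples)"
        )
    breakdown = {
        "pcr1_fwd": n_pcr1_fwd,
        "pcr1_rev": n_pcr1_rev,
        "pcr2_fwd": 1,
        "pcr2_rev": n_plates,
    }
    return SchemeCost(n_samples=n_samples, plate_size=plate_size, breakdown=breakdown)


def count_oligos_dual_alternative(n_samples: int) -> SchemeCost:
    """Oligo cost of a two-step dual-index scheme multiplexing the same samples.

    Two universal (unindexed) PCR1 primers plus the smallest i + j indexed
    PCR2 forward/reverse sets with i*j >= n_samples.  Because sample capacity
    is the product i*j, the oligo count grows like 2*sqrt(n) rather than
    linearly with plates.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    best_i, best_j = 1, n_samples
    # i + ceil(n/i) is minimized near sqrt(n); scanning i up to sqrt(n) covers
    # every factor-pair shape once by symmetry.
    for i in range(1, math.isqrt(n_samples) + 2):
        j = math.ceil(n_samples / i)
        if i + j < best_i + best_j:
            best_i, best_j = i, j
    breakdown = {
        "pcr1_fwd": 1,
        "pcr1_rev": 1,
        "pcr2_fwd": best_i,
        "pcr2_rev": best_j,
    }
    return SchemeCost(n_samples=n_samples, plate_size=DEFAULT_PLATE_SIZE, breakdown=breakdown)


def positional_base_composition(
    layout: PlateLayout,
    scheme: SchemeSpec,
    prefix_len: int,
    directions: Sequence[str] = ("forward", "reverse"),
) -> pd.DataFrame:
    """Per-sequencing-cycle A/C/G/T fractions over the read starts of a layout.

    Every well contributes its read-start construct (barcode + spacer +
    priming) for each requested mate direction, equally weighted.  Degenerate
    IUPAC positions in the priming sequence contribute fractionally to each
    base they expand to.  Positions beyond a construct's end are excluded from
    that construct's contribution, so each returned row still sums to 1.

    Returns a DataFrame indexed by position (1-based) with columns A, C, G, T.
    """
    if prefix_len <= 0:
        raise ValueError("prefix_len must be positive")
    constructs: list[str] = []
    for well in layout.wells:
        if "forward" in directions:
            constructs.append(scheme.read_start_construct(scheme.barcodes[well.fwd]))
        if "reverse" in directions:
            constructs.append(scheme.read_start_construct(scheme.barcodes[well.rev]))
    if not constructs:
        raise ValueError("layout has no wells")

    rows = []
    for pos in range(prefix_len):
        counts = {b: 0.0 for b in "ACGT"}
        n_contrib = 0
        for c in constructs:
            if pos >= len(c):
                continue
            n_contrib += 1
            expansion = IUPAC_CODES[c[pos]]
            w = 1.0 / len(expansion)
            for b in expansion:
                counts[b] += w
        if n_contrib == 0:
            rows.append({b: float("nan") for b in "ACGT"})
        else:
            rows.append({b: counts[b] / n_contrib for b in "ACGT"})
    df = pd.DataFrame(rows, index=pd.RangeIndex(1, prefix_len + 1, name="position"))
    return df


# ---------------------------------------------------------------------------
# Primer table I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["name", "direction", "adapter", "barcode", "spacer", "priming", "full_oligo"]


def load_primer_table(path) -> SchemeSpec:
    """Load a primer/barcode TSV into a :class:`SchemeSpec`.

    Expected columns: name, direction, adapter, barcode, spacer, priming,
    full_oligo.  Rows with direction forward/reverse define internal barcodes;
    pcr2_forward/pcr2_reverse rows define the second-stage primers.  Each
    row's ``full_oligo`` is validated against the concatenation of its parts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"primer table missing columns: {sorted(missing)}")

    bad = df[df.adapter + df.barcode + df.spacer + df.priming != df.full_oligo]
    if not bad.empty:
        raise ValueError(
            f"full_oligo does not equal adapter+barcode+spacer+priming for rows: "
            f"{bad.name.tolist()}"
        )

    entries = [
        BarcodeEntry(r.name, r.barcode, r.spacer, r.direction)
        for r in df.itertuples()
        if r.direction in ("forward", "reverse")
    ]
    barcodes = BarcodeSet(entries)

    def _one(direction: str) -> pd.Series:
        sub = df[df.direction == direction]
        if sub.empty:
            raise ValueError(f"primer table has no {direction} row")
        return sub.iloc[0]

    fwd_row = _one("forward")
    rev_row = _one("reverse")
    p2f = _one("pcr2_forward")
    p2r = df[df.direction == "pcr2_reverse"]
    if p2r.empty:
        raise ValueError("primer table has no pcr2_reverse rows")
    parts = PrimerParts(
        partial_adapter_fwd=fwd_row.adapter,
        partial_adapter_rev=rev_row.adapter,
        priming_fwd=fwd_row.priming,
        priming_rev=rev_row.priming,
        pcr2_adapter_fwd=p2f.adapter,
        pcr2_adapter_rev=p2r.iloc[0].adapter,
        pcr2_indices=tuple(p2r.barcode),
    )
    return SchemeSpec(parts=parts, barcodes=barcodes)


def write_primer_table(scheme: SchemeSpec, path) -> None:
    """Write a :class:`SchemeSpec` back to the TSV layout of ``load_primer_table``."""
    rows = []
    for e in scheme.barcodes:
        adapter = (
            scheme.parts.partial_adapter_fwd
            if e.direction == "forward"
            else scheme.parts.partial_adapter_rev
        )
        priming = (
            scheme.parts.priming_fwd if e.direction == "forward" else scheme.parts.priming_rev
        )
        rows.append((e.name, e.direction, adapter, e.sequence, e.spacer, priming,
                     adapter + e.sequence + e.spacer + priming))
    p = scheme.parts
    rows.append(("pcr2_f", "pcr2_forward", p.pcr2_adapter_fwd, "", "",
                 p.partial_adapter_fwd, p.pcr2_adapter_fwd + p.partial_adapter_fwd))
    tail = reverse_complement(p.partial_adapter_rev)
    for k, idx in enumerate(p.pcr2_indices):
        rows.append((f"i{k + 1}", "pcr2_reverse", p.pcr2_adapter_rev, idx, "", tail,
                     p.pcr2_adapter_rev + idx + tail))
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def default_scheme() -> SchemeSpec:
    """The scheme shipped with the package (synthetic 12 fwd + 8 rev barcode table)."""
    with resources.as_file(
        resources.files("trindex.data").joinpath("primers_default.tsv")
    ) as path:
        return load_primer_table(path)
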