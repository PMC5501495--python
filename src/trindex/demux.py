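"""Dual internal-barcode demultiplexing, trimming and paired-read merging.

Sample identity is resolved from three indices: the pool-level 6-nt PCR2
index (already separated by the sequencer's own demultiplexing; supplied here
as a label per input file pair or as a ``pool=`` token in read headers), plus
the 12-nt internal barcodes at the start of read 1 (forward) and read 2
(reverse).  After barcode lookup the heterogeneity spacer and the degenerate
V4 priming sequence are stripped, mates are merged over their 3' overlap into
a single V4 fragment, and any read-through reverse-primer tail is trimmed.
"""

from __future__ import annotations

import gzip
import json
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .oligo_design import (
    IUPAC_CODES,
    BarcodeSet,
    MAX_SPACER_LEN,
    SchemeSpec,
    reverse_complement,
)

# ---------------------------------------------------------------------------
# Configuration and result types
# ---------------------------------------------------------------------------

#: Unassignment reasons recorded in :class:`DemuxStats`.
REASONS = ("bad_fwd_barcode", "bad_rev_barcode", "bad_primer", "no_samplesheet_entry")


@dataclass
class DemuxConfig:
    """Tolerances for barcode/primer matching and read-pair merging.

    ``barcode_mismatch_max`` must stay below half the minimum pairwise
    Hamming distance of the barcode set so that mismatch-tolerant decoding
    stays unambiguous; this is checked against each barcode set used.
    """

    barcode_mismatch_max: int = 0
    primer_mismatch_frac: float = 0.1
    spacer_mode: str = "lookup"  # "lookup" | "scan"
    min_overlap: int = 10
    merge_mismatch_frac: float = 0.25
    barcode_before_spacer: bool = True  # read layout: barcode then spacer (else swapped)
    swap_mates: bool = False  # True when read 1 carries the reverse barcode

    def __post_init__(self) -> None:
        for name in ("primer_mismatch_frac", "merge_mismatch_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.spacer_mode not in ("lookup", "scan"):
            raise ValueError(f"spacer_mode must be 'lookup' or 'scan', got {self.spacer_mode!r}")
        if self.barcode_mismatch_max < 0:
            raise ValueError("barcode_mismatch_max must be >= 0")

    def check_decodable(self, barcodes: BarcodeSet) -> None:
        """Reject barcode sets whose spacing cannot support the mismatch budget."""
        d = barcodes.min_pairwise_hamming()
        if not self.barcode_mismatch_max < d / 2:
            raise ValueError(
                f"barcode_mismatch_max={self.barcode_mismatch_max} is not uniquely "
                f"decodable for a set with minimum pairwise Hamming distance {d}"
            )


@dataclass
class SampleSheet:
    """Triple key (pool index, fwd barcode name, rev barcode name) -> sample id."""

    rows: list[tuple[str, str, str, str]]  # (pool_index, fwd, rev, sample_id)

    def __post_init__(self) -> None:
        keys = [(p, f, r) for p, f, r, _ in self.rows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (pool, fwd, rev) key in sample sheet")
        self._lookup = {(p, f, r): s for p, f, r, s in self.rows}

    def __len__(self) -> int:
        return len(self.rows)

    def get(self, pool_index: str, fwd: str, rev: str) -> str | None:
        return self._lookup.get((pool_index, fwd, rev))

    def sample_ids(self) -> list[str]:
        return [s for _, _, _, s in self.rows]

    def validate_against(self, barcodes: BarcodeSet) -> None:
        names = set(barcodes.names())
        for _, f, r, s in self.rows:
            if f not in names or r not in names:
                raise ValueError(f"sample {s}: barcode {f!r}/{r!r} not in barcode set")

    @classmethod
    def from_file(cls, path) -> "SampleSheet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        need = {"pool_index", "fwd_barcode", "rev_barcode", "sample_id"}
        if not need <= set(df.columns):
            raise ValueError(f"sample sheet must have columns {sorted(need)}")
        return cls([(r.pool_index, r.fwd_barcode, r.rev_barcode, r.sample_id)
                    for r in df.itertuples()])

    def to_file(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.rows, columns=["pool_index", "fwd_barcode", "rev_barcode",
                                         "sample_id"]).to_csv(path, sep="\t", index=False)


@dataclass
class DemuxStats:
    """Assignment bookkeeping with a conservation invariant.

    total_pairs == sum(assigned per sample) + sum(unassigned per reason), and
    when merging is enabled merged + merge_failed == assigned pairs.
    """

    total_pairs: int = 0
    assigned: Counter = field(default_factory=Counter)
    unassigned: Counter = field(default_factory=Counter)
    merged: int = 0
    merge_failed: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(self.assigned.values())

    @property
    def n_unassigned(self) -> int:
        return sum(self.unassigned.values())

    def check_conservation(self, merging: bool = False) -> None:
        if self.total_pairs != self.n_assigned + self.n_unassigned:
            raise AssertionError(
                f"conservation violated: {self.total_pairs} pairs != "
                f"{self.n_assigned} assigned + {self.n_unassigned} unassigned"
            )
        if merging and self.merged + self.merge_failed != self.n_assigned:
            raise AssertionError(
                f"merge conservation violated: {self.merged} + {self.merge_failed} "
                f"!= {self.n_assigned}"
            )

    def to_dict(self) -> dict:
        return {
            "total_pairs": self.total_pairs,
            "assigned": dict(self.assigned),
            "unassigned": dict(self.unassigned),
            "merged": self.merged,
            "merge_failed": self.merge_failed,
        }


@dataclass
class ParsedStart:
    barcode: str
    spacer_len: int
    insert_offset: int


@dataclass
class DemuxResult:
    """Per-sample outputs of a demultiplexing run."""

    stats: DemuxStats
    pairs: dict[str, list[tuple[str, str, str, str, str]]]  # sample -> (id, s1, q1, s2, q2)
    fragments: dict[str, list[tuple[str, str]]]  # sample -> (read id, merged fragment)


# ---------------------------------------------------------------------------
# Matching primitives
# ---------------------------------------------------------------------------

def iupac_match(pattern: str, seq: str, max_mismatch: int = 0) -> tuple[bool, int]:
    """Match ``seq`` against an IUPAC-degenerate ``pattern`` of equal length.

    A position matches when the concrete base is in the expansion of the
    pattern code.  Returns ``(n_mismatch <= max_mismatch, n_mismatch)``.
    """
    if len(pattern) != len(seq):
        raise ValueError(f"length mismatch: pattern {len(pattern)} vs seq {len(seq)}")
    n_mismatch = 0
    for p, s in zip(pattern, seq):
        try:
            expansion = IUPAC_CODES[p]
        except KeyError:
            raise ValueError(f"non-IUPAC character {p!r} in pattern") from None
        if s not in expansion:
            n_mismatch += 1
    return n_mismatch <= max_mismatch, n_mismatch


def _match_barcode(
    prefix: str, candidates: list, max_mismatch: int
) -> object | None:
    """Nearest barcode within the mismatch budget (None when all exceed it)."""
    best, best_d = None, max_mismatch + 1
    for entry in candidates:
        d = sum(a != b for a, b in zip(entry.sequence, prefix))
        if d < best_d:
            best, best_d = entry, d
            if d == 0:
                break
    return best


def parse_read_start(
    seq: str,
    direction: str,
    scheme: SchemeSpec,
    cfg: DemuxConfig,
) -> ParsedStart | str:
    """Resolve (barcode, spacer length, insert offset) at the start of a read.

    Returns a :class:`ParsedStart` or a failure reason string
    (``bad_fwd_barcode``/``bad_rev_barcode``/``bad_primer``).  In ``lookup``
    spacer mode the spacer length comes from the barcode's table entry; in
    ``scan`` mode lengths 0..7 are tried until the priming sequence matches.
    """
    barcodes = scheme.barcodes.subset(direction)
    priming = scheme.parts.priming_fwd if direction == "forward" else scheme.parts.priming_rev
    bad_barcode = "bad_fwd_barcode" if direction == "forward" else "bad_rev_barcode"
    bc_len = barcodes.barcode_length(direction)
    if len(seq) <= bc_len + MAX_SPACER_LEN + len(priming):
        return bad_barcode

    primer_budget = int(cfg.primer_mismatch_frac * len(priming))

    if cfg.barcode_before_spacer:
        entry = _match_barcode(seq[:bc_len], barcodes.entries, cfg.barcode_mismatch_max)
        if entry is None:
            return bad_barcode
        if cfg.spacer_mode == "lookup":
            spacer_lens = [len(entry.spacer)]
        else:
            spacer_lens = list(range(MAX_SPACER_LEN + 1))
        for sl in spacer_lens:
            off = bc_len + sl
            ok, _ = iupac_match(priming, seq[off:off + len(priming)], primer_budget)
            if ok:
                return ParsedStart(entry.name, sl, off + len(priming))
        return "bad_primer"

    # Spacer-before-barcode layout: the spacer length is unknown until the
    # barcode is located, so slide the barcode window over lengths 0..7
    # (lookup mode additionally requires the table's paired length to agree).
    found = False
    for sl in range(MAX_SPACER_LEN + 1):
        entry = _match_barcode(seq[sl:sl + bc_len], barcodes.entries, cfg.barcode_mismatch_max)
        if entry is None:
            continue
        if cfg.spacer_mode == "lookup" and len(entry.spacer) != sl:
            continue
        found = True
        off = sl + bc_len
        ok, _ = iupac_match(priming, seq[off:off + len(priming)], primer_budget)
        if ok:
            return ParsedStart(entry.name, sl, off + len(priming))
    return "bad_primer" if found else bad_barcode


def demultiplex_pair(
    r1: tuple[str, str, str],
    r2: tuple[str, str, str],
    pool_index: str,
    sheet: SampleSheet,
    scheme: SchemeSpec,
    cfg: DemuxConfig,
) -> tuple[str, tuple[str, str, str], tuple[str, str, str]] | str:
    """Assign one read pair to a sample and trim both mates to their inserts.

    ``r1``/``r2`` are (id, sequence, quality).  Returns
    ``(sample_id, trimmed_r1, trimmed_r2)`` or an unassignment reason.
    """
    if cfg.swap_mates:
        r1, r2 = r2, r1
    p1 = parse_read_start(r1[1], "forward", scheme, cfg)
    if isinstance(p1, str):
        return p1
    p2 = parse_read_start(r2[1], "reverse", scheme, cfg)
    if isinstance(p2, str):
        return p2
    sample = sheet.get(pool_index, p1.barcode, p2.barcode)
    if sample is None:
        return "no_samplesheet_entry"
    t1 = (r1[0], r1[1][p1.insert_offset:], r1[2][p1.insert_offset:])
    t2 = (r2[0], r2[1][p2.insert_offset:], r2[2][p2.insert_offset:])
    return sample, t1, t2


def merge_pair(
    r1_seq: str,
    r1_qual: str,
    r2_seq: str,
    r2_qual: str,
    cfg: DemuxConfig,
) -> tuple[str, str] | None:
    """Merge trimmed mates over their 3' overlap into one fragment.

    Read 2 is reverse-complemented first.  Candidate overlaps from
    ``min(len1, len2)`` down to ``min_overlap`` are scored by mismatch
    fraction; the lowest fraction (largest overlap on ties) wins, provided it
    is <= ``merge_mismatch_frac``.  Disagreeing bases take the higher-quality
    call; agreeing bases take the higher of the two qualities.
    """
    if not r1_seq or not r2_seq:
        return None
    s2 = reverse_complement(r2_seq)
    q2 = r2_qual[::-1]
    a1 = np.frombuffer(r1_seq.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    max_ov = min(len(a1), len(a2))
    if max_ov < cfg.min_overlap:
        return None

    best_k, best_frac = None, np.inf
    for k in range(max_ov, cfg.min_overlap - 1, -1):
        mism = int(np.count_nonzero(a1[len(a1) - k:] != a2[:k]))
        frac = mism / k
        if frac < best_frac:
            best_frac, best_k = frac, k
            if mism == 0:
                break
    if best_k is None or best_frac > cfg.merge_mismatch_frac:
        return None

    k = best_k
    left_s, left_q = r1_seq[:len(r1_seq) - k], r1_qual[:len(r1_qual) - k]
    right_s, right_q = s2[k:], q2[k:]
    ov_s, ov_q = [], []
    o1s, o1q = r1_seq[len(r1_seq) - k:], r1_qual[len(r1_qual) - k:]
    o2s, o2q = s2[:k], q2[:k]
    for b1, c1, b2, c2 in zip(o1s, o1q, o2s, o2q):
        if c2 > c1:
            ov_s.append(b2)
        else:
            ov_s.append(b1)
        ov_q.append(max(c1, c2))
    return left_s + "".join(ov_s) + right_s, left_q + "".join(ov_q) + right_q


def trim_trailing_primer(
    merged: str, rev_priming: str, cfg: DemuxConfig
) -> tuple[str, bool]:
    """Remove a read-through reverse-priming site from the 3' end if present.

    The site appears as the reverse complement of the reverse primer at the
    fragment end; it is removed when it matches within the primer mismatch
    budget.  Idempotent: applying the trim twice changes nothing more.
    Returns ``(fragment, was_trimmed)``.
    """
    site = reverse_complement(rev_priming)
    if len(merged) <= len(site):
        return merged, False
    budget = int(cfg.primer_mismatch_frac * len(site))
    ok, _ = iupac_match(site, merged[-len(site):], budget)
    if ok:
        return merged[:-len(site)], True
    return merged, False


# ---------------------------------------------------------------------------
# File-level driver
# ---------------------------------------------------------------------------

def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(r1_path, r2_path) -> Iterator[tuple[tuple, tuple]]:
    """Iterate synchronized (id, seq, qual) tuples from two FASTQ files."""
    with _open_text(r1_path) as h1, _open_text(r2_path) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2, strict=True):
            yield (t1, s1, q1), (t2, s2, q2)


def pool_from_header(title: str) -> str | None:
    """Extract a ``pool=<label>`` token from a FASTQ title line, if present."""
    for tok in title.split():
        if tok.startswith("pool="):
            return tok[5:]
    return None


def demultiplex_run(
    pairs: Iterable[tuple[tuple, tuple]],
    pool_index: str | None,
    sheet: SampleSheet,
    scheme: SchemeSpec,
    cfg: DemuxConfig | None = None,
    merge: bool = True,
    keep_pairs: bool = False,
) -> DemuxResult:
    """Demultiplex an iterable of read pairs into per-sample fragments.

    ``pool_index=None`` takes each pair's pool from a ``pool=`` header token.
    When ``merge`` is on, trimmed mates are merged and read-through reverse
    primer tails trimmed; merged fragments are collected per sample.
    """
    cfg = cfg or DemuxConfig()
    cfg.check_decodable(scheme.forward)
    cfg.check_decodable(scheme.reverse)
    sheet.validate_against(scheme.barcodes)

    stats = DemuxStats()
    result = DemuxResult(stats=stats, pairs={}, fragments={})
    for r1, r2 in pairs:
        stats.total_pairs += 1
        pool = pool_index if pool_index is not None else pool_from_header(r1[0])
        if pool is None:
            stats.unassigned["no_samplesheet_entry"] += 1
            continue
        out = demultiplex_pair(r1, r2, pool, sheet, scheme, cfg)
        if isinstance(out, str):
            stats.unassigned[out] += 1
            continue
        sample, t1, t2 = out
        stats.assigned[sample] += 1
        if keep_pairs:
            result.pairs.setdefault(sample, []).append((t1[0], t1[1], t1[2], t2[1], t2[2]))
        if merge:
            m = merge_pair(t1[1], t1[2], t2[1], t2[2], cfg)
            if m is None:
                stats.merge_failed += 1
            else:
                stats.merged += 1
                frag, _ = trim_trailing_primer(m[0], scheme.parts.priming_rev, cfg)
                result.fragments.setdefault(sample, []).append((t1[0], frag))
    stats.check_conservation(merging=merge)
    return result


def write_demux_outputs(result: DemuxResult, out_dir) -> None:
    """Write per-sample pair FASTQ / merged FASTA plus stats TSV and JSON."""
    os.makedirs(out_dir, exist_ok=True)
    for sample, recs in result.pairs.items():
        with open(os.path.join(out_dir, f"{sample}_R1.fastq"), "w") as h1, \
                open(os.path.join(out_dir, f"{sample}_R2.fastq"), "w") as h2:
            for rid, s1, q1, s2, q2 in recs:
                h1.write(f"@{rid}\n{s1}\n+\n{q1}\n")
                h2.write(f"@{rid}\n{s2}\n+\n{q2}\n")
    for sample, frags in result.fragments.items():
        with open(os.path.join(out_dir, f"{sample}_merged.fasta"), "w") as fh:
            for rid, frag in frags:
                fh.write(f">{rid}\n{frag}\n")
    stats = result.stats
    with open(os.path.join(out_dir, "demux_stats.json"), "w") as fh:
        json.dump(stats.to_dict(), fh, indent=2)
    with open(os.path.join(out_dir, "demux_stats.tsv"), "w") as fh:
        fh.write("category\tkey\tcount\n")
        fh.write(f"input\ttotal_pairs\t{stats.total_pairs}\n")
        for sample, n in sorted(stats.assigned.items()):
            fh.write(f"assigned\t{sample}\t{n}\n")
        for reason, n in sorted(stats.unassigned.items()):
            fh.write(f"unassigned\t{reason}\t{n}\n")
        fh.write(f"merge\tmerged\t{stats.merged}\n")
        fh.write(f"merge\tmerge_failed\t{stats.merge_failed}\n")
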