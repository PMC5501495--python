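"""Mock-community benchmarking statistics.

Implements the evaluation applied to demultiplexed, merged V4 fragments:
exact-identity read assignment against a small reference of known fragments
(the "full-length alignment at 100% identity" criterion reduces to string
equality once primers are trimmed), OTU-table construction, common scaling
and rare-OTU filtering, accuracy and bias estimators (deviation from the
equal-blending expectation, abundance-vs-GC regression, chimera statistics),
and Bray-Curtis variance partitioning via PERMANOVA (adonis-style sequential
sums of squares) and ANOSIM.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .oligo_design import gc_fraction, reverse_complement


# ---------------------------------------------------------------------------
# Reference and OTU table
# ---------------------------------------------------------------------------

class ReferenceDB:
    """Exact-lookup reference: V4 fragment sequence -> species id.

    Both orientations of every fragment are indexed.  Duplicate fragments are
    rejected because they would make assignment ambiguous.
    """

    def __init__(self, entries: Iterable[tuple[str, str]]):
        self.entries = [(sid, seq.upper()) for sid, seq in entries]
        seqs = [s for _, s in self.entries]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate fragment sequences in reference")
        self.gc = {sid: gc_fraction(seq) for sid, seq in self.entries}
        self._lookup: dict[str, str] = {}
        for sid, seq in self.entries:
            rc = reverse_complement(seq)
            for key in (seq, rc):
                if key in self._lookup and self._lookup[key] != sid:
                    raise ValueError(f"fragment of {sid} collides with {self._lookup[key]}")
                self._lookup[key] = sid

    def __len__(self) -> int:
        return len(self.entries)

    def species_ids(self) -> list[str]:
        return [sid for sid, _ in self.entries]

    def lookup(self, fragment: str) -> str | None:
        return self._lookup.get(fragment.upper())

    @classmethod
    def from_fasta(cls, path) -> "ReferenceDB":
        from Bio import SeqIO

        return cls((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta"))

    @classmethod
    def from_template_set(cls, template_set) -> "ReferenceDB":
        return cls((t.species_id, t.sequence) for t in template_set.templates)


def assign_reads(
    fragments: Iterable[str], ref: ReferenceDB
) -> tuple[Counter, int]:
    """Count fragments per species by exact full-length identity.

    A fragment counts for a species iff it equals that species' reference
    fragment in either orientation; everything else is unassigned.
    """
    counts: Counter = Counter()
    unassigned = 0
    for frag in fragments:
        if isinstance(frag, tuple):  # (read id, sequence) pairs from demux
            frag = frag[1]
        sid = ref.lookup(frag)
        if sid is None:
            unassigned += 1
        else:
            counts[sid] += 1
    return counts, unassigned


@dataclass
class OtuTable:
    """Samples x species count matrix with per-sample metadata factors."""

    counts: pd.DataFrame  # rows = samples, columns = species, non-negative ints
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts in OTU table")
        if not self.metadata.empty and not set(self.counts.index) <= set(self.metadata.index):
            raise ValueError("metadata does not cover all samples")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        sizes = self.library_sizes
        if (sizes == 0).any():
            raise ValueError("sample with zero reads cannot be normalized")
        return self.counts.div(sizes, axis=0)


def otu_table_from_fragments(
    fragments_by_sample: Mapping[str, Iterable[str]],
    ref: ReferenceDB,
    metadata: pd.DataFrame | None = None,
) -> tuple[OtuTable, pd.Series]:
    """Assign every sample's fragments and build the OTU table.

    Returns the table plus a per-sample unassigned-read count.
    """
    species = ref.species_ids()
    rows, unassigned = {}, {}
    for sample, frags in fragments_by_sample.items():
        c, u = assign_reads(frags, ref)
        rows[sample] = [c.get(s, 0) for s in species]
        unassigned[sample] = u
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=species)
    table = OtuTable(counts=counts, metadata=metadata if metadata is not None else pd.DataFrame())
    return table, pd.Series(unassigned, name="unassigned")


# ---------------------------------------------------------------------------
# Scaling and filtering
# ---------------------------------------------------------------------------

def common_scale(table: OtuTable) -> pd.DataFrame:
    """Scale every library to the smallest library size.

    Each row is multiplied by min(sizes) / own size, the deterministic
    alternative to rarefying (it equals the expectation over infinitely many
    random sub-samplings).  No rounding is applied.
    """
    sizes = table.library_sizes
    if table.counts.empty:
        raise ValueError("empty OTU table")
    if (sizes <= 0).any():
        raise ValueError("all library sizes must be > 0")
    return table.counts.mul(sizes.min() / sizes, axis=0)


def filter_rare(
    rel: pd.DataFrame, threshold: float = 1e-4, renormalize: bool = False
) -> pd.DataFrame:
    """Drop OTU columns whose mean relative abundance is below ``threshold``.

    ``threshold`` defaults to 0.01%.  Remaining values are unchanged unless
    ``renormalize`` is requested, in which case rows are rescaled to sum to 1.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    keep = rel.mean(axis=0) >= threshold
    out = rel.loc[:, keep]
    if renormalize:
        out = out.div(out.sum(axis=1), axis=0)
    return out


# ---------------------------------------------------------------------------
# Accuracy / bias estimators
# ---------------------------------------------------------------------------

def mean_abs_deviation_from_expected(
    rel: pd.DataFrame, expected: pd.Series
) -> dict:
    """Accuracy of abundance estimates against a known blending expectation.

    Returns, in percentage points: ``overall`` = mean over species of
    |mean observed - expected| x 100, plus per-species observed means and
    standard deviations.
    """
    if set(rel.columns) != set(expected.index):
        raise ValueError("species mismatch between table and expectation")
    if abs(expected.sum() - 1.0) > 1e-9:
        raise ValueError("expected proportions must sum to 1")
    expected = expected.reindex(rel.columns)
    per_species_mean = rel.mean(axis=0)
    per_species_sd = rel.std(axis=0, ddof=1)
    dev_pp = (per_species_mean - expected).abs() * 100.0
    return {
        "overall": float(dev_pp.mean()),
        "per_species_deviation_pp": dev_pp,
        "per_species_mean": per_species_mean,
        "per_species_sd": per_species_sd,
    }


def gc_bias_slope(
    mean_rel_pct: Sequence[float], gc_pct: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of mean relative abundance (%) on fragment GC content (%).

    Returns (slope per GC percentage point, intercept, two-sided p for the
    slope).  A negative slope quantifies under-amplification of GC-rich
    fragments.
    """
    gc = np.asarray(gc_pct, dtype=float)
    y = np.asarray(mean_rel_pct, dtype=float)
    if len(gc) < 3:
        raise ValueError("need at least 3 species")
    if np.ptp(gc) == 0:
        raise ValueError("GC content is constant; slope undefined")
    res = sps.linregress(gc, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)


def chimera_stats(truth: pd.DataFrame) -> tuple[float, float]:
    """Per-sample chimera burden from a ground-truth table.

    Returns (chimeric-read fraction, singleton-chimera fraction).  The
    singleton fraction is the share of distinct chimeric identities observed
    exactly once; it is NaN when the sample has no chimeras.  Distinct
    chimeric identities are keyed by (parents, breakpoint), the simulator's
    definition of a distinct chimeric sequence.
    """
    n = len(truth)
    if n == 0:
        return 0.0, float("nan")
    chim = truth[truth["is_chimera"].astype(bool)]
    frac = len(chim) / n
    if chim.empty:
        return frac, float("nan")
    key_counts = chim.groupby(["parents", "breakpoint"]).size()
    singleton = (key_counts == 1).sum() / len(key_counts)
    return float(frac), float(singleton)


def chimera_cycle_regression(
    cycles: Sequence[float], chimera_fracs: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of per-sample chimera fraction on PCR cycle number.

    Returns (slope per cycle, R^2, two-sided p).  Linearity of chimera burden
    in cycle number is the signature of per-cycle template switching.
    """
    x = np.asarray(cycles, dtype=float)
    y = np.asarray(chimera_fracs, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct cycle values")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.rvalue ** 2), float(res.pvalue)


# ---------------------------------------------------------------------------
# Distances and variance partitioning
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with sample labels.

    Bray-Curtis on non-negative data: entries in [0, 1], zero diagonal.
    Semimetric — the triangle inequality is not asserted.
    """

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("distances outside [0, 1]")
        self.values = v

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def bray_curtis_matrix(rel: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample abundance rows.

    d(i, j) = 1 - 2 * sum_k min(x_ik, x_jk) / sum_k (x_ik + x_jk).
    """
    x = rel.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative data")
    if (x.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample row; distance undefined")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(values=d, ids=list(rel.index))


def _gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G from a distance matrix."""
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    """Projection (hat) matrix onto the column space of x."""
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _design_columns(values: pd.Series) -> np.ndarray:
    """Full-rank dummy coding (drop-first) for one categorical factor."""
    d = pd.get_dummies(values.astype("category"), drop_first=True, dtype=float)
    return d.to_numpy()


def permanova_r2(
    dm: DistanceMatrix,
    grouping: pd.Series | pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a distance matrix (adonis-style).

    Partitions the total sum of squared distances via the Gower-centered
    matrix; with several factors (DataFrame columns) sequential sums of
    squares are used in the given column order, so R^2 per factor depends on
    entry order unless the design is balanced and orthogonal.  p-values come
    from ``n_perm`` random permutations of the sample labels (pseudo-F
    compared against the observed value, with the +1 correction).

    Returns a DataFrame indexed by factor (plus a Residual row) with columns
    df, SS, R2, pseudo_F and p_value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = (
        grouping.to_frame() if isinstance(grouping, pd.Series) else grouping.copy()
    )
    labels = labels.loc[dm.ids]
    n = len(dm)
    if n < 3:
        raise ValueError("need at least 3 samples")
    for col in labels.columns:
        # A single-level factor is degenerate but well defined: it explains
        # nothing (SS = 0, R^2 = 0).  A factor with one level per sample
        # saturates the model and leaves no residual.
        if labels[col].nunique() >= n:
            raise ValueError(f"factor {col!r} has one level per sample")

    g = _gower_center(dm.values)
    ss_total = float(np.trace(g))

    # Sequential hats: H_0 = intercept only, then each factor added in order.
    ones = np.ones((n, 1))
    design = ones
    hats = [_hat(design)]
    dfs: list[int] = []
    for col in labels.columns:
        cols = _design_columns(labels[col])
        design = np.hstack([design, cols])
        h = _hat(design)
        dfs.append(int(round(np.trace(h) - np.trace(hats[-1]))))
        hats.append(h)

    def _sequential_ss(gmat: np.ndarray) -> np.ndarray:
        tr = np.array([float(np.sum(h * gmat)) for h in hats])  # tr(H G), H symmetric
        return np.diff(tr)

    ss_factors = _sequential_ss(g)
    df_resid = n - int(round(np.trace(hats[-1])))
    ss_resid = ss_total - float(np.sum(hats[-1] * g))
    if df_resid <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    ms_resid = ss_resid / df_resid

    def _pseudo_f(ss: float, df: int, ms: float) -> float:
        if df == 0:
            return np.nan
        return (ss / df) / ms if ms > 0 else np.inf

    f_obs = np.array([_pseudo_f(ss, df, ms_resid) for ss, df in zip(ss_factors, dfs)])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(dfs))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ssp = _sequential_ss(gp)
        ssp_resid = float(np.trace(gp)) - float(np.sum(hats[-1] * gp))
        msp = ssp_resid / df_resid
        fp = np.array([_pseudo_f(ss, df, msp) for ss, df in zip(ssp, dfs)])
        with np.errstate(invalid="ignore"):
            exceed += np.where(np.isnan(f_obs), 0, fp >= f_obs)
    pvals = (exceed + 1) / (n_perm + 1)

    rows = []
    for col, df_k, ss_k, f_k, p_k in zip(labels.columns, dfs, ss_factors, f_obs, pvals):
        rows.append({"factor": col, "df": df_k, "SS": ss_k,
                     "R2": ss_k / ss_total if ss_total > 0 else 0.0,
                     "pseudo_F": f_k,
                     "p_value": p_k if not np.isnan(f_k) else np.nan})
    rows.append({"factor": "Residual", "df": df_resid, "SS": ss_resid,
                 "R2": ss_resid / ss_total if ss_total > 0 else 0.0,
                 "pseudo_F": np.nan, "p_value": np.nan})
    return pd.DataFrame(rows).set_index("factor")


def anosim(
    dm: DistanceMatrix,
    grouping: pd.Series | Sequence[str],
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Analysis of similarities: rank-based between- vs within-group contrast.

    R = (mean rank of between-group distances - mean rank of within-group
    distances) / (M / 2), with M = n(n-1)/2 pairwise distances mid-ranked for
    ties.  R near 1 means complete separation, near 0 no group structure.
    The p-value permutes group labels ``n_perm`` times (+1 correction).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = pd.Series(list(grouping), index=dm.ids) if not isinstance(grouping, pd.Series) \
        else grouping.loc[dm.ids]
    if labels.nunique() < 2:
        raise ValueError("need at least 2 groups")
    n = len(dm)
    iu = np.triu_indices(n, k=1)
    ranks = sps.rankdata(dm.values[iu])
    m = len(ranks)
    codes = pd.Categorical(labels).codes

    def _r(codes_arr: np.ndarray) -> float:
        within = codes_arr[iu[0]] == codes_arr[iu[1]]
        return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2))

    r_obs = _r(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _r(perm) >= r_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return r_obs, float(p)


def spearman_matrix(rel: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation between sample abundance vectors.

    Constant vectors have undefined rank correlation and yield NaN against
    every other sample; the diagonal is 1 for non-constant samples.
    """
    if rel.shape[1] < 2:
        raise ValueError("need at least 2 species")
    # pandas corr(method="spearman") silently yields values for constant
    # vectors in some versions; rank first and use Pearson on ranks.
    ranked = rel.rank(axis=1)
    constant = ranked.nunique(axis=1) == 1
    out = ranked.T.corr(method="pearson")
    out.loc[constant, :] = np.nan
    out.loc[:, constant] = np.nan
    return out
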