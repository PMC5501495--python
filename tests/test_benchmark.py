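"""Assignment, scaling/filtering, bias estimators and variance partitioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import trindex as tx
from trindex.oligo_design import reverse_complement


# ---------------------------------------------------------------------------
# Exact-identity assignment
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def ref(small_templates=None):
    ts = tx.make_mock_templates(n_species=4, length=100, gc_min=0.4, gc_max=0.6, seed=5)
    return tx.ReferenceDB.from_template_set(ts)


def test_exact_match_assigns_and_one_substitution_does_not(ref):
    sid, frag = ref.entries[0]
    counts, unassigned = tx.assign_reads([frag], ref)
    assert counts == {sid: 1} and unassigned == 0
    mutated = ("C" if frag[0] != "C" else "G") + frag[1:]
    counts, unassigned = tx.assign_reads([mutated], ref)
    assert counts == {} and unassigned == 1


def test_reverse_orientation_matches(ref):
    sid, frag = ref.entries[2]
    counts, _ = tx.assign_reads([reverse_complement(frag)], ref)
    assert counts == {sid: 1}


def test_reference_rejects_duplicate_fragments():
    with pytest.raises(ValueError, match="duplicate"):
        tx.ReferenceDB([("a", "ACGTACGT"), ("b", "ACGTACGT")])


def test_assignment_matches_simulator_truth(scheme, small_templates):
    pool = tx.simulate_pcr(small_templates,
                           tx.PcrParams(cycles1=10, cycles2=0, capacity=100_000),
                           seed=8, initial_copies=200)
    well = tx.WellAssignment("i1", scheme.barcodes["f2"], scheme.barcodes["r4"])
    reads, truth = tx.sample_reads(pool, 500, well, scheme, "S", read_len=110, seed=9)
    result = tx.demultiplex_run(
        [((t, s1, q1), (t, s2, q2)) for t, s1, q1, s2, q2 in reads],
        "i1", tx.SampleSheet([("i1", "f2", "r4", "S")]), scheme, merge=True,
    )
    refdb = tx.ReferenceDB.from_template_set(small_templates)
    table, unassigned = tx.otu_table_from_fragments(result.fragments, refdb)
    assert unassigned.sum() == 0
    truth_counts = truth.groupby("parents").size()
    for species in table.counts.columns:
        assert table.counts.loc["S", species] == truth_counts.get(species, 0)


# ---------------------------------------------------------------------------
# Scaling and filtering
# ---------------------------------------------------------------------------

def test_common_scale_halves_larger_library():
    t = tx.OtuTable(counts=pd.DataFrame({"a": [60, 120], "b": [40, 80]},
                                        index=["s1", "s2"]))
    scaled = tx.common_scale(t)
    assert np.allclose(scaled.loc["s1"], [60, 40])
    assert np.allclose(scaled.loc["s2"], [60, 40])


def test_common_scale_identity_for_equal_sizes():
    t = tx.OtuTable(counts=pd.DataFrame({"a": [10, 20], "b": [30, 20]},
                                        index=["s1", "s2"]))
    assert np.allclose(tx.common_scale(t).values, t.counts.values)


def test_common_scale_row_sums_equal_min(rng):
    counts = pd.DataFrame(rng.integers(1, 500, size=(5, 10)),
                          index=[f"s{i}" for i in range(5)])
    t = tx.OtuTable(counts=counts)
    scaled = tx.common_scale(t)
    assert np.allclose(scaled.sum(axis=1), t.library_sizes.min())


def test_filter_rare_drops_only_below_threshold():
    rel = pd.DataFrame({
        "abundant": [0.5, 0.6, 0.4, 0.5],
        "borderline": [0.49985, 0.39985, 0.59985, 0.49985],
        "rare": [5e-5, 5e-5, 5e-5, 5e-5],
        "absent": [0.0, 0.0, 0.0, 0.0],
    }, index=list("wxyz"))
    rel["borderline"] += (1e-4 - rel["borderline"].mean() / len(rel))  # keep >= 1e-4
    out = tx.filter_rare(rel, threshold=1e-4)
    assert list(out.columns) == ["abundant", "borderline"]
    pd.testing.assert_frame_equal(out, rel[["abundant", "borderline"]])


def test_filter_rare_renormalized_rows_sum_to_one(rng):
    raw = pd.DataFrame(rng.random(size=(6, 20)) + 0.05)
    raw.iloc[:, 3] = 1e-6   # one clearly rare OTU
    raw.iloc[:, 11] = 1e-6
    rel = raw.div(raw.sum(axis=1), axis=0)
    out = tx.filter_rare(rel, threshold=1e-3, renormalize=True)
    assert out.shape[1] < 20
    assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# Accuracy and bias estimators
# ---------------------------------------------------------------------------

def test_deviation_zero_when_observed_equals_expected():
    rel = pd.DataFrame({"a": [0.5, 0.5], "b": [0.5, 0.5]})
    expected = pd.Series({"a": 0.5, "b": 0.5})
    assert tx.mean_abs_deviation_from_expected(rel, expected)["overall"] == 0.0


def test_deviation_in_percentage_points():
    rel = pd.DataFrame({"a": [0.04, 0.04], "b": [0.02, 0.02], "c": [0.94, 0.94]})
    expected = pd.Series({"a": 0.03, "b": 0.03, "c": 0.94})
    out = tx.mean_abs_deviation_from_expected(rel, expected)
    # species a and b each deviate by 1 percentage point, c by 0
    assert out["overall"] == pytest.approx((1.0 + 1.0 + 0.0) / 3)
    assert out["per_species_deviation_pp"]["a"] == pytest.approx(1.0)


def test_deviation_rejects_mismatched_species():
    rel = pd.DataFrame({"a": [1.0]})
    with pytest.raises(ValueError, match="mismatch"):
        tx.mean_abs_deviation_from_expected(rel, pd.Series({"b": 1.0}))


def test_gc_slope_recovers_constructed_line_exactly():
    gc = np.linspace(30, 69, 33)
    abund = 10.0 - 0.18 * gc
    slope, intercept, p = tx.gc_bias_slope(abund, gc)
    assert slope == pytest.approx(-0.18, abs=1e-12)
    assert intercept == pytest.approx(10.0, abs=1e-9)
    assert p < 1e-10


def test_gc_slope_flat_and_three_point():
    slope, _, _ = tx.gc_bias_slope([3.0, 3.0, 3.0, 3.0], [30, 40, 50, 60])
    assert slope == pytest.approx(0.0, abs=1e-12)
    slope, intercept, _ = tx.gc_bias_slope([4.0, 3.0, 2.0], [40.0, 50.0, 60.0])
    assert slope == pytest.approx(-0.1, abs=1e-12)  # closed-form OLS on 3 points
    with pytest.raises(ValueError, match="constant"):
        tx.gc_bias_slope([1.0, 2.0, 3.0], [50.0, 50.0, 50.0])


def _truth_frame(rows):
    return pd.DataFrame(rows, columns=["parents", "breakpoint", "is_chimera"])


def test_chimera_stats_no_chimeras():
    truth = _truth_frame([("sp1", -1, False)] * 10)
    frac, singleton = tx.chimera_stats(truth)
    assert frac == 0.0 and np.isnan(singleton)


def test_chimera_stats_singleton_fraction():
    rows = [("sp1", -1, False)] * 83
    # 10 distinct chimeras, 9 seen once, one seen 8 times -> 17/100 chimeric reads
    rows += [(f"sp1+sp{k}", 10 + k, True) for k in range(2, 11)]
    rows += [("sp1+sp12", 99, True)] * 8
    truth = _truth_frame(rows)
    frac, singleton = tx.chimera_stats(truth)
    assert frac == pytest.approx(0.17)
    assert singleton == pytest.approx(0.9)


def test_chimera_cycle_regression_exact_line_and_flat():
    cycles = [25, 25, 30, 30, 35, 35]
    slope, r2, p = tx.chimera_cycle_regression(cycles, [0.01 * c for c in cycles])
    assert slope == pytest.approx(0.01, abs=1e-12)
    assert r2 == pytest.approx(1.0)
    slope, r2, _ = tx.chimera_cycle_regression(cycles, [0.2] * 6)
    assert slope == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="distinct"):
        tx.chimera_cycle_regression([25, 25, 30], [0.1, 0.2, 0.3])


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def test_bray_curtis_identical_disjoint_and_hand_value():
    rel = pd.DataFrame([[2.0, 1.0], [2.0, 1.0], [0.0, 3.0], [1.0, 3.0]],
                       index=list("abcd"), columns=["x", "y"])
    dm = tx.bray_curtis_matrix(rel)
    d = dm.to_frame()
    assert d.loc["a", "b"] == pytest.approx(0.0)
    disjoint = tx.bray_curtis_matrix(pd.DataFrame([[1.0, 0.0], [0.0, 1.0]],
                                                  index=["p", "q"]))
    assert disjoint.to_frame().loc["p", "q"] == pytest.approx(1.0)
    # rows (2,1) and (1,3): 1 - 2*(1+1)/(3+4) = 3/7
    assert d.loc["a", "d"] == pytest.approx(3 / 7)


def test_bray_curtis_matrix_invariants(rng):
    for _ in range(5):
        rel = pd.DataFrame(rng.random(size=(7, 12)))
        dm = tx.bray_curtis_matrix(rel)
        v = dm.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0.0)
        assert (v >= 0).all() and (v <= 1).all()


def test_bray_curtis_rejects_invalid_rows():
    with pytest.raises(ValueError, match="non-negative"):
        tx.bray_curtis_matrix(pd.DataFrame([[1.0, -0.1], [0.5, 0.5]]))
    with pytest.raises(ValueError, match="zero"):
        tx.bray_curtis_matrix(pd.DataFrame([[0.0, 0.0], [0.5, 0.5]]))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _brute_force_r2(dm: tx.DistanceMatrix, labels: pd.Series) -> float:
    """SS_total - SS_within over explicit pairwise sums of squared distances."""
    d = dm.values
    n = len(dm)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in labels.unique():
        idx = [k for k, s in enumerate(dm.ids) if labels[s] == g]
        ss_within += sum(
            d[i, j] ** 2 for a, i in enumerate(idx) for j in idx[a + 1:]
        ) / len(idx)
    return (ss_total - ss_within) / ss_total


def test_permanova_r2_one_for_duplicated_groups():
    rel = pd.DataFrame([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]],
                       index=list("abcd"))
    dm = tx.bray_curtis_matrix(rel)
    res = tx.permanova_r2(dm, pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd")),
                          n_perm=99, seed=0)
    assert res.iloc[0]["R2"] == pytest.approx(1.0)


def test_permanova_single_group_explains_nothing(rng):
    rel = pd.DataFrame(rng.random(size=(5, 4)), index=list("abcde"))
    dm = tx.bray_curtis_matrix(rel)
    res = tx.permanova_r2(dm, pd.Series(["g"] * 5, index=list("abcde"), name="f"),
                          n_perm=9, seed=0)
    assert res.loc["f", "R2"] == pytest.approx(0.0, abs=1e-12)


def test_permanova_matches_brute_force_oracle(rng):
    for trial in range(10):
        rel = pd.DataFrame(rng.random(size=(6, 8)), index=[f"s{i}" for i in range(6)])
        labels = pd.Series(rng.permutation(["a", "a", "b", "b", "c", "c"]),
                           index=rel.index, name="grp")
        dm = tx.bray_curtis_matrix(rel)
        res = tx.permanova_r2(dm, labels, n_perm=9, seed=trial)
        assert res.loc["grp", "R2"] == pytest.approx(_brute_force_r2(dm, labels),
                                                     abs=1e-9)


def test_permanova_sequential_components_bounded_and_order_stable(rng):
    # balanced orthogonal 2x2 design, 3 replicates -> 12 samples
    idx = [f"s{i}" for i in range(12)]
    f1 = pd.Series(["x", "y"] * 6, index=idx, name="f1")
    f2 = pd.Series(["u"] * 6 + ["v"] * 6, index=idx, name="f2")
    rel = pd.DataFrame(rng.random(size=(12, 10)), index=idx)
    dm = tx.bray_curtis_matrix(rel)
    a = tx.permanova_r2(dm, pd.concat([f1, f2], axis=1), n_perm=9, seed=1)
    b = tx.permanova_r2(dm, pd.concat([f2, f1], axis=1), n_perm=9, seed=1)
    assert a.loc[["f1", "f2"], "R2"].sum() <= 1.0 + 1e-12
    assert a.loc["f1", "R2"] == pytest.approx(b.loc["f1", "R2"], abs=1e-9)
    assert a.loc["f2", "R2"] == pytest.approx(b.loc["f2", "R2"], abs=1e-9)
    # all components plus residual partition the total exactly
    assert a["R2"].sum() == pytest.approx(1.0, abs=1e-9)


def test_permanova_detects_real_group_structure(rng):
    base = np.vstack([np.tile([5.0, 1.0, 0.1, 0.1], (6, 1)),
                      np.tile([0.1, 0.1, 1.0, 5.0], (6, 1))])
    rel = pd.DataFrame(base + rng.random((12, 4)) * 0.2,
                       index=[f"s{i}" for i in range(12)])
    labels = pd.Series(["A"] * 6 + ["B"] * 6, index=rel.index, name="grp")
    dm = tx.bray_curtis_matrix(rel)
    res = tx.permanova_r2(dm, labels, n_perm=999, seed=2)
    assert res.loc["grp", "R2"] > 0.8
    assert res.loc["grp", "p_value"] < 0.01


def test_permanova_agrees_with_skbio(rng):
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    from skbio import DistanceMatrix as SkbioDM

    for trial in range(3):
        rel = pd.DataFrame(rng.random(size=(12, 9)), index=[f"s{i}" for i in range(12)])
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        dm = tx.bray_curtis_matrix(rel)
        ours = tx.permanova_r2(dm, pd.Series(labels, index=rel.index, name="g"),
                               n_perm=99, seed=trial)
        theirs = skbio_stats.permanova(SkbioDM(dm.values, ids=dm.ids), labels,
                                       permutations=99)
        # identical pseudo-F implies identical SS partition
        assert ours.loc["g", "pseudo_F"] == pytest.approx(theirs["test statistic"],
                                                          abs=1e-3)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def test_anosim_full_separation_is_one():
    # all between-group distances exceed all within-group distances
    d = np.array([
        [0.0, 0.1, 0.9, 0.8],
        [0.1, 0.0, 0.85, 0.95],
        [0.9, 0.85, 0.0, 0.15],
        [0.8, 0.95, 0.15, 0.0],
    ])
    dm = tx.DistanceMatrix(values=d, ids=list("abcd"))
    r, p = tx.anosim(dm, ["g1", "g1", "g2", "g2"], n_perm=999, seed=0)
    assert r == pytest.approx(1.0)


def test_anosim_matches_hand_ranked_oracle():
    d = np.array([
        [0.0, 0.2, 0.5, 0.7],
        [0.2, 0.0, 0.6, 0.4],
        [0.5, 0.6, 0.0, 0.3],
        [0.7, 0.4, 0.3, 0.0],
    ])
    dm = tx.DistanceMatrix(values=d, ids=list("abcd"))
    # pairwise distances: ab=.2 ac=.5 ad=.7 bc=.6 bd=.4 cd=.3
    # ranks:              1     4     6     5     3     2
    # within (ab, cd): mean rank 1.5; between: mean rank 4.5; M/2 = 3
    r, _ = tx.anosim(dm, ["g1", "g1", "g2", "g2"], n_perm=9, seed=0)
    assert r == pytest.approx((4.5 - 1.5) / 3)


def test_anosim_null_centers_on_zero(rng):
    rs = []
    for s in range(50):
        rel = pd.DataFrame(rng.random(size=(8, 6)), index=[f"s{i}" for i in range(8)])
        dm = tx.bray_curtis_matrix(rel)
        labels = list(rng.permutation(["a"] * 4 + ["b"] * 4))
        r, _ = tx.anosim(dm, pd.Series(labels, index=rel.index), n_perm=1, seed=s)
        rs.append(r)
    assert abs(np.mean(rs)) < 0.1


def test_anosim_agrees_with_skbio(rng):
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    from skbio import DistanceMatrix as SkbioDM

    rel = pd.DataFrame(rng.random(size=(10, 7)), index=[f"s{i}" for i in range(10)])
    labels = ["a"] * 5 + ["b"] * 5
    dm = tx.bray_curtis_matrix(rel)
    r, _ = tx.anosim(dm, pd.Series(labels, index=rel.index), n_perm=9, seed=0)
    theirs = skbio_stats.anosim(SkbioDM(dm.values, ids=dm.ids), labels, permutations=9)
    assert r == pytest.approx(theirs["test statistic"], abs=1e-9)


# ---------------------------------------------------------------------------
# Spearman matrix
# ---------------------------------------------------------------------------

def test_spearman_matrix_identical_reversed_and_hand_value():
    rel = pd.DataFrame({
        "sp1": [0.5, 0.5, 0.1],
        "sp2": [0.3, 0.3, 0.3],
        "sp3": [0.2, 0.2, 0.6],
    }, index=["a", "b", "c"])
    m = tx.spearman_matrix(rel)
    assert m.loc["a", "b"] == pytest.approx(1.0)   # identical vectors
    assert m.loc["a", "c"] == pytest.approx(-1.0)  # exactly reversed ranks
    expected, _ = sps.spearmanr(rel.loc["a"], rel.loc["c"])
    assert m.loc["a", "c"] == pytest.approx(expected)


def test_spearman_matrix_constant_vector_is_missing():
    third = 1.0 / 3.0
    rel = pd.DataFrame({"sp1": [third, 0.25], "sp2": [third, 0.25], "sp3": [third, 0.5]},
                       index=["flat", "vary"])
    m = tx.spearman_matrix(rel)
    assert np.isnan(m.loc["flat", "vary"])
    assert np.isnan(m.loc["vary", "flat"])
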