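"""Recruitment normalizations, UniFrac/PCoA/ANOSIM, and abundance regressions."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import anosim as skbio_anosim

from ecophys.recruit import (
    AbundanceMatrix,
    abundance_regression,
    anosim,
    log_transform,
    pcoa,
    regress_all,
    rpkm,
    tpm,
    weighted_unifrac,
)
from ecophys.simulate import simulate_tree
from oracles import anosim_exact_p_brute_force, anosim_r_brute_force, unifrac_brute_force


def _matrix(counts, lengths, libsizes):
    genomes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    return AbundanceMatrix(
        counts=pd.DataFrame(counts, index=genomes, columns=samples),
        genome_lengths=pd.Series(lengths, index=genomes),
        library_sizes=pd.Series(libsizes, index=samples),
    )


# ------------------------------------------------------------------- RPKM


def test_rpkm_unit_arithmetic():
    m = _matrix(np.array([[1000.0], [0.0]]), [2e6, 1e6], [1e6])
    table = rpkm(m)
    assert table.iloc[0, 0] == pytest.approx(0.5)
    assert table.iloc[1, 0] == 0.0


def test_rpkm_matches_elementwise_hand_computation():
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 5000, size=(5, 4)).astype(float)
    lengths = rng.uniform(1e6, 3e6, size=5)
    libsizes = rng.uniform(1e5, 1e7, size=4)
    table = rpkm(_matrix(counts, lengths, libsizes)).to_numpy()
    for g in range(5):
        for s in range(4):
            expected = counts[g, s] / ((lengths[g] / 1e3) * (libsizes[s] / 1e6))
            assert table[g, s] == pytest.approx(expected, rel=1e-12)


def test_rpkm_zero_library_size_rejected():
    m = _matrix(np.zeros((2, 1)), [1e6, 1e6], [0.0])
    with pytest.raises(ValueError, match="zero library"):
        rpkm(m)


def test_abundance_matrix_invariants():
    with pytest.raises(ValueError, match="nonnegative"):
        _matrix(np.array([[-1.0]]), [1e6], [1e3])
    with pytest.raises(ValueError, match="library sizes"):
        _matrix(np.array([[100.0]]), [1e6], [10.0])
    with pytest.raises(ValueError, match="lengths"):
        _matrix(np.array([[1.0]]), [0.0], [1e3])


def test_rpkm_and_tpm_invariant_to_duplicating_a_sample():
    rng = np.random.default_rng(9)
    counts = rng.integers(0, 1000, size=(4, 3)).astype(float)
    counts = np.hstack([counts, counts[:, [0]]])  # duplicate first sample
    m = _matrix(counts, rng.uniform(1e6, 2e6, 4), [1e6, 2e6, 5e5, 1e6])
    r = rpkm(m)
    t = tpm(m)
    np.testing.assert_allclose(r.iloc[:, 0], r.iloc[:, 3])
    np.testing.assert_allclose(t.iloc[:, 0], t.iloc[:, 3])


# -------------------------------------------------------------------- TPM


def test_tpm_columns_sum_to_one_million():
    rng = np.random.default_rng(2)
    counts = rng.integers(0, 500, size=(6, 5)).astype(float)
    counts[:, 2] = 0.0  # all-zero sample stays all-zero
    m = _matrix(counts, rng.uniform(1e6, 3e6, 6), np.full(5, 1e6))
    table = tpm(m)
    sums = table.sum(axis=0).to_numpy()
    np.testing.assert_allclose(sums[[0, 1, 3, 4]], 1e6, rtol=1e-9)
    assert sums[2] == 0.0


def test_tpm_single_genome_column_and_hand_computation():
    m = _matrix(np.array([[10.0], [0.0]]), [1e6, 2e6], [1e5])
    assert tpm(m).iloc[0, 0] == pytest.approx(1e6)
    # 3-genome worked column: counts 10, 20, 30; lengths 1, 2, 3 Mbp
    # rates = 10/1000, 20/2000, 30/3000 = 0.01 each -> TPM = 1e6/3 each
    m3 = _matrix(np.array([[10.0], [20.0], [30.0]]), [1e6, 2e6, 3e6], [1e5])
    np.testing.assert_allclose(tpm(m3).iloc[:, 0], 1e6 / 3.0, rtol=1e-12)


# ---------------------------------------------------------- log transform


def test_log_transform_values_and_monotonicity():
    df = pd.DataFrame({"s": [1.0, 0.0, 10.0, 0.3]})
    with np.errstate(divide="ignore"):
        out = log_transform(df, pseudocount=0.0)
    assert out.iloc[0, 0] == pytest.approx(0.0)
    assert np.isinf(out.iloc[1, 0])  # pseudocount 0 leaves zeros at -inf
    default = log_transform(df)  # half the smallest nonzero entry = 0.15
    assert np.isfinite(default.to_numpy()).all()
    assert default.iloc[1, 0] == pytest.approx(np.log10(0.15))
    order_in = df["s"].rank()
    order_out = default["s"].rank()
    pd.testing.assert_series_equal(order_in, order_out)


def test_log_transform_rejects_negatives():
    with pytest.raises(ValueError):
        log_transform(pd.DataFrame({"s": [-0.1]}))
    with pytest.raises(ValueError, match="all-zero"):
        log_transform(pd.DataFrame({"s": [0.0]}))


# ----------------------------------------------------------- UniFrac


def _abund(d: dict) -> pd.DataFrame:
    return pd.DataFrame(d).rename_axis("genome")


def test_unifrac_identical_profiles_distance_zero():
    tree = TreeNode.read(["((A:1,B:2):0.5,(C:1,D:1):0.5);"])
    table = _abund({"s1": [1.0, 2.0, 3.0, 0.0], "s2": [1.0, 2.0, 3.0, 0.0]})
    table.index = ["A", "B", "C", "D"]
    dm = weighted_unifrac(tree, table)
    assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-12)


def test_unifrac_disjoint_two_tip_communities_maximal():
    tree = TreeNode.read(["(A:1,B:1);"])
    table = _abund({"s1": [4.0, 0.0], "s2": [0.0, 9.0]})
    table.index = ["A", "B"]
    dm = weighted_unifrac(tree, table, normalized=True)
    assert dm["s1", "s2"] == pytest.approx(1.0, abs=1e-12)


def test_unifrac_four_tip_hand_evaluation():
    # branch-by-branch hand sums for proportions s1 = {A:.5, B:.5} and
    # s2 = {A:.25, C:.75}: raw = 2.75, denominator = 3.5
    tree = TreeNode.read(["((A:1,B:2):0.5,(C:1,D:1):0.5);"])
    table = _abund({"s1": [2.0, 2.0, 0.0, 0.0], "s2": [1.0, 0.0, 3.0, 0.0]})
    table.index = ["A", "B", "C", "D"]
    raw = weighted_unifrac(tree, table, normalized=False)
    norm = weighted_unifrac(tree, table, normalized=True)
    assert raw["s1", "s2"] == pytest.approx(2.75, abs=1e-12)
    assert norm["s1", "s2"] == pytest.approx(2.75 / 3.5, abs=1e-12)


def test_unifrac_missing_genome_named():
    tree = TreeNode.read(["(A:1,B:1);"])
    table = _abund({"s1": [1.0, 1.0], "s2": [1.0, 0.0]})
    table.index = ["A", "Z"]
    with pytest.raises(ValueError, match="Z"):
        weighted_unifrac(tree, table)


@pytest.mark.parametrize("seed", range(10))
def test_unifrac_matches_brute_force_on_random_trees(seed):
    rng = np.random.default_rng(seed)
    tree = simulate_tree(6, seed=seed)
    names = [t.name for t in tree.tips()]
    counts = rng.integers(0, 50, size=(6, 2)).astype(float)
    counts[:, 0] += 1  # keep communities nonempty
    counts[:, 1] += rng.integers(0, 2, size=6)
    if counts[:, 1].sum() == 0:
        counts[0, 1] = 1
    table = pd.DataFrame(counts, index=names, columns=["s1", "s2"])
    prop = table / table.sum(axis=0)
    raw_oracle, norm_oracle = unifrac_brute_force(
        tree, prop["s1"].to_dict(), prop["s2"].to_dict()
    )
    raw = weighted_unifrac(tree, table, normalized=False)["s1", "s2"]
    norm = weighted_unifrac(tree, table, normalized=True)["s1", "s2"]
    assert raw == pytest.approx(raw_oracle, abs=1e-10)
    assert norm == pytest.approx(norm_oracle, abs=1e-10)
    assert 0.0 <= norm <= 1.0


def test_raw_unifrac_triangle_inequality_on_random_trees():
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        tree = simulate_tree(5, seed=seed)
        names = [t.name for t in tree.tips()]
        counts = rng.integers(1, 30, size=(5, 3)).astype(float)
        table = pd.DataFrame(counts, index=names, columns=["a", "b", "c"])
        dm = weighted_unifrac(tree, table, normalized=False)
        for x, y, z in [("a", "b", "c"), ("a", "c", "b"), ("b", "c", "a")]:
            assert dm[x, y] <= dm[x, z] + dm[z, y] + 1e-10


# --------------------------------------------------------------- PCoA


def test_pcoa_recovers_points_on_a_line():
    x = np.array([0.0, 1.0, 3.0, 7.0])
    d = np.abs(x[:, None] - x[None, :])
    coords, eigvals = pcoa(DistanceMatrix(d, ids=list("abcd")), n_axes=1)
    axis = coords.iloc[:, 0].to_numpy()
    got = np.abs(axis[:, None] - axis[None, :])
    np.testing.assert_allclose(got, d, atol=1e-8)


def test_pcoa_euclidean_round_trip():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(6, 2))
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    ids = [f"s{i}" for i in range(6)]
    coords, eigvals = pcoa(DistanceMatrix(d, ids=ids), n_axes=2)
    emb = coords.to_numpy()
    got = np.linalg.norm(emb[:, None, :] - emb[None, :, :], axis=-1)
    np.testing.assert_allclose(got, d, atol=1e-8)


def test_pcoa_equilateral_distances_give_equal_eigenvalues():
    d = np.ones((3, 3)) - np.eye(3)
    coords, eigvals = pcoa(DistanceMatrix(d, ids=list("abc")), n_axes=2)
    assert eigvals.iloc[0] == pytest.approx(eigvals.iloc[1], rel=1e-9)


def test_pcoa_truncates_with_warning():
    d = np.ones((3, 3)) - np.eye(3)
    with pytest.warns(UserWarning, match="truncating"):
        coords, _ = pcoa(DistanceMatrix(d, ids=list("abc")), n_axes=5)
    assert coords.shape[1] <= 2


# -------------------------------------------------------------- ANOSIM


def _separated_distances():
    # two tight clusters far apart: every between-pair exceeds every within-pair
    within = 0.1
    d = np.full((6, 6), 5.0)
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                d[i, j] = 0.0 if i == j else within
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])


def test_anosim_perfect_separation_r_is_one():
    dm = _separated_distances()
    labels = ["x", "x", "x", "y", "y", "y"]
    res = anosim(dm, labels, n_permutations=199, seed=0)
    assert res.R == pytest.approx(1.0)
    assert res.p_value <= 0.05 or res.p_value == pytest.approx(0.1, abs=0.1)


def test_anosim_exact_matches_brute_force_enumeration():
    rng = np.random.default_rng(8)
    pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(1.5, 1, (3, 2))])
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
    labels = ["a", "a", "a", "b", "b", "b"]
    res = anosim(dm, labels, exact=True)
    r_oracle, p_oracle = anosim_exact_p_brute_force(d, labels)
    assert res.R == pytest.approx(r_oracle, abs=1e-12)
    assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
    assert res.method == "exact"


def test_anosim_monte_carlo_agrees_with_exact_within_binomial_error():
    rng = np.random.default_rng(12)
    pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(1.0, 1, (3, 2))])
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
    labels = ["a", "a", "a", "b", "b", "b"]
    p_exact = anosim(dm, labels, exact=True).p_value
    mc = anosim(dm, labels, n_permutations=4999, seed=3)
    se = np.sqrt(p_exact * (1 - p_exact) / 4999)
    assert abs(mc.p_value - p_exact) < 4 * se + 1e-3


def test_anosim_cross_checked_against_skbio():
    rng = np.random.default_rng(21)
    pts = np.vstack([rng.normal(0, 1, (4, 3)), rng.normal(2.0, 1, (4, 3))])
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    ids = [f"s{i}" for i in range(8)]
    dm = DistanceMatrix(d, ids=ids)
    labels = ["a"] * 4 + ["b"] * 4
    ours = anosim(dm, labels, n_permutations=999, seed=0)
    theirs = skbio_anosim(dm, list(labels), permutations=999, seed=0)
    assert ours.R == pytest.approx(theirs["test statistic"], abs=1e-12)
    assert abs(ours.p_value - theirs["p-value"]) < 0.05
    assert ours.R == pytest.approx(anosim_r_brute_force(d, labels), abs=1e-12)


def test_anosim_rejects_degenerate_groupings():
    dm = _separated_distances()
    with pytest.raises(ValueError, match="2 groups"):
        anosim(dm, ["x"] * 6)
    with pytest.raises(ValueError, match="fewer than 2"):
        anosim(dm, ["x", "x", "x", "x", "x", "y"])


def test_anosim_r_bounds():
    dm = _separated_distances()
    res = anosim(dm, ["x", "y", "x", "y", "x", "y"], n_permutations=99, seed=1)
    assert -1.0 <= res.R <= 1.0


# -------------------------------------------------------- OLS regressions


def test_regression_exact_line():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    r = abundance_regression(-2.0 * x + 1.0, x)
    assert r.slope == pytest.approx(-2.0, abs=1e-12)
    assert r.intercept == pytest.approx(1.0, abs=1e-12)
    assert r.p_value < 1e-10
    assert r.r_squared == pytest.approx(1.0)


def test_regression_five_point_hand_ols():
    # classic hand computation: slope 0.6, intercept 2.2
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 4.0, 5.0, 4.0, 5.0])
    r = abundance_regression(y, x)
    assert r.slope == pytest.approx(0.6, abs=1e-12)
    assert r.intercept == pytest.approx(2.2, abs=1e-12)


def test_regression_input_validation():
    with pytest.raises(ValueError, match="zero variance"):
        abundance_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
    with pytest.raises(ValueError, match="3 paired"):
        abundance_regression([1.0, 2.0], [1.0, 2.0])


def test_regress_all_with_bh_adjustment():
    rng = np.random.default_rng(17)
    x = np.linspace(0, 10, 12)
    table = pd.DataFrame(
        {f"s{i}": None for i in range(12)},
        index=["gA", "gB", "gC"],
        dtype=float,
    )
    table.loc["gA"] = -1.5 * x + rng.normal(0, 0.1, 12)
    table.loc["gB"] = rng.normal(0, 1, 12)
    table.loc["gC"] = 0.5 * x + rng.normal(0, 0.1, 12)
    out = regress_all(table, x, adjust=True)
    assert out.loc["gA", "slope"] == pytest.approx(-1.5, abs=0.1)
    assert "q_value" in out.columns
    assert (out["q_value"] >= out["p_value"] - 1e-12).all()
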