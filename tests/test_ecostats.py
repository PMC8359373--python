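"""Ecology statistics against exhaustive-enumeration oracles and analytic
identities: rarefaction, accumulation, Raup-Crick, PERMANOVA, dispersion
homogeneity, transforms, UPGMA, richness ANOVA, trophic aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import cophenet
from scipy.stats import norm, t as t_dist, ttest_ind

from dungdna import (
    CommunityMatrix,
    DistanceMatrix,
    accumulation_exact,
    cube_transform,
    dispersion_test,
    inverse_normal_distances,
    inverse_normal_transform,
    permanova,
    rarefaction_curve,
    raup_crick,
    raup_crick_pair,
    richness_anova,
    trophic_aggregate,
    upgma,
)
from dungdna.io_core import ValidationError
from conftest import random_distance_matrix
from oracles import (
    brute_accumulation,
    brute_permanova_exhaustive,
    brute_raup_crick,
    brute_rarefaction,
    brute_upgma_cophenetic,
    permanova_f_r2,
)


def community(presence: np.ndarray, habitats=None) -> CommunityMatrix:
    n, m = presence.shape
    df = pd.DataFrame(presence, index=[f"s{i}" for i in range(n)],
                      columns=[f"t{j}" for j in range(m)])
    habs = habitats or {f"s{i}": "x" for i in range(n)}
    return CommunityMatrix(df, habs)


# ---- rarefaction ----------------------------------------------------------


def test_rarefaction_full_sample_and_single_read_limits():
    counts = np.array([10, 5, 2, 0])
    full = rarefaction_curve(counts, [17])
    assert full["expected_richness"].iloc[0] == pytest.approx(3.0, abs=1e-10)
    one = rarefaction_curve(counts, [1])
    assert one["expected_richness"].iloc[0] == pytest.approx(1.0, abs=1e-10)


def test_rarefaction_small_case_exact_fraction():
    # counts (2,1,1), n=2: E[S] = 5/6 + 1/2 + 1/2 = 11/6
    out = rarefaction_curve([2, 1, 1], [2])
    assert out["expected_richness"].iloc[0] == pytest.approx(11 / 6, abs=1e-12)


def test_rarefaction_effort_beyond_total_rejected():
    with pytest.raises(ValidationError):
        rarefaction_curve([2, 1], [4])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_rarefaction_matches_enumeration_up_to_12_reads(seed):
    rng = np.random.default_rng(seed)
    while True:
        counts = rng.integers(0, 5, size=rng.integers(1, 5))
        if 0 < counts.sum() <= 12:
            break
    total = int(counts.sum())
    n = int(rng.integers(1, total + 1))
    expected = brute_rarefaction(counts.tolist(), n)
    got = rarefaction_curve(counts, [n])["expected_richness"].iloc[0]
    assert got == pytest.approx(expected, abs=1e-9)


def test_rarefaction_monotone_in_effort_at_depth():
    """Expected richness is non-decreasing in effort and bounded by the
    observed richness, at realistic read depths (log-space stability)."""
    rng = np.random.default_rng(0)
    counts = rng.integers(1, 200_000, size=50)
    efforts = np.unique(np.linspace(1, counts.sum(), 25, dtype=np.int64))
    curve = rarefaction_curve(counts, efforts)
    vals = curve["expected_richness"].to_numpy()
    assert (np.diff(vals) >= -1e-9).all()
    assert vals[-1] == pytest.approx(50, abs=1e-6)


# ---- accumulation ---------------------------------------------------------


def test_accumulation_limits():
    pres = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 1]])
    curve = accumulation_exact(community(pres), sd_permutations=0)
    assert curve["expected_richness"].iloc[-1] == pytest.approx(3.0)  # t = T
    assert curve["expected_richness"].iloc[0] == pytest.approx((2 + 1 + 1) / 3)  # t = 1


def test_accumulation_three_site_hand_case():
    # sites {A}, {A,B}, {C}: mean over pairs = (2 + 2 + 3) / 3 = 7/3
    pres = np.array([[1, 0, 0], [1, 1, 0], [0, 0, 1]])
    curve = accumulation_exact(community(pres), sd_permutations=0)
    assert curve["expected_richness"].iloc[1] == pytest.approx(7 / 3, abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_accumulation_matches_enumeration_up_to_6_sites(seed):
    rng = np.random.default_rng(seed)
    T = int(rng.integers(1, 7))
    S = int(rng.integers(1, 8))
    pres = (rng.random((T, S)) < 0.5).astype(int)
    pres[0, 0] = 1  # keep at least one taxon
    curve = accumulation_exact(community(pres), sd_permutations=0)
    for t in range(1, T + 1):
        assert curve["expected_richness"].iloc[t - 1] == pytest.approx(
            brute_accumulation(pres, t), abs=1e-9
        )


def test_accumulation_sd_is_seeded_and_zero_at_full_effort():
    pres = (np.random.default_rng(1).random((5, 12)) < 0.4).astype(int)
    pres[0, 0] = 1
    a = accumulation_exact(community(pres), sd_permutations=200, seed=9)
    b = accumulation_exact(community(pres), sd_permutations=200, seed=9)
    pd.testing.assert_frame_equal(a, b)
    assert a["sd"].iloc[-1] == pytest.approx(0.0, abs=1e-12)


# ---- Raup-Crick -----------------------------------------------------------


def test_raup_crick_disjoint_samples_give_one():
    pres = np.array([[1, 1, 0, 0], [0, 0, 1, 1]])
    d = raup_crick(community(pres))
    assert d.values[0, 1] == pytest.approx(1.0)


def test_raup_crick_small_case_exact():
    # S=4, a=b=2, j=1: 1 - C(2,0)C(2,2)/C(4,2) = 5/6
    assert raup_crick_pair(2, 2, 1, 4) == pytest.approx(5 / 6, abs=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_raup_crick_matches_enumeration_on_small_pools(seed):
    rng = np.random.default_rng(seed)
    pool = int(rng.integers(2, 13))
    a = int(rng.integers(1, pool + 1))
    b = int(rng.integers(1, pool + 1))
    j = int(rng.integers(0, min(a, b) + 1))
    if j < max(0, a + b - pool):  # impossible overlap
        j = max(0, a + b - pool)
    assert raup_crick_pair(a, b, j, pool) == pytest.approx(
        brute_raup_crick(a, b, j, pool), abs=1e-10
    )


def test_raup_crick_decreases_as_sharing_increases():
    vals = [raup_crick_pair(5, 5, j, 20) for j in range(6)]
    assert all(vals[i] > vals[i + 1] for i in range(5))


def test_raup_crick_invariant_to_row_and_column_order():
    rng = np.random.default_rng(2)
    pres = (rng.random((5, 9)) < 0.5).astype(int)
    pres[:, 0] = 1
    cm = community(pres)
    d = raup_crick(cm)
    perm_taxa = rng.permutation(pres.shape[1])
    cm2 = community(pres[:, perm_taxa])
    np.testing.assert_allclose(raup_crick(cm2).values, d.values, atol=1e-12)
    perm_samples = rng.permutation(pres.shape[0])
    d3 = raup_crick(community(pres[perm_samples]))
    np.testing.assert_allclose(
        d3.values, d.values[np.ix_(perm_samples, perm_samples)], atol=1e-12
    )


def test_raup_crick_monte_carlo_null_agreement():
    """The analytic tail probability matches a Monte-Carlo draw of the
    hypergeometric null (random b-subsets of the pool) within 3 SE."""
    rng = np.random.default_rng(123)
    pool, a, b, j = 30, 12, 10, 6
    n_draws = 100_000
    first = np.zeros(pool, dtype=bool)
    first[:a] = True
    hits = 0
    for _ in range(n_draws):
        draw = rng.choice(pool, size=b, replace=False)
        if first[draw].sum() >= j:
            hits += 1
    p_mc = hits / n_draws
    p_exact = raup_crick_pair(a, b, j, pool)
    se = np.sqrt(p_exact * (1 - p_exact) / n_draws)
    assert abs(p_mc - p_exact) <= 3 * se


# ---- PERMANOVA ------------------------------------------------------------


def test_permanova_perfect_separation_r2_is_one():
    d = np.ones((4, 4)) - np.eye(4)
    d[0, 1] = d[1, 0] = 0.0
    d[2, 3] = d[3, 2] = 0.0
    res = permanova(DistanceMatrix(d, list("abcd")), ["g1", "g1", "g2", "g2"], 99, seed=1)
    assert res.R2 == pytest.approx(1.0)


def test_permanova_matches_exhaustive_brute_force_hand_case():
    """Two groups of two, within-distance 0.2 and between 0.9: F, R2 and
    the exact permutation p must match full enumeration."""
    d = np.full((4, 4), 0.9)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 0.2
    d[2, 3] = d[3, 2] = 0.2
    labels = ["g1", "g1", "g2", "g2"]
    f_b, r2_b, p_b = brute_permanova_exhaustive(d, labels)
    res = permanova(DistanceMatrix(d, list("abcd")), labels, 999, seed=0)
    assert res.F == pytest.approx(f_b, rel=1e-12)
    assert res.R2 == pytest.approx(r2_b, rel=1e-12)
    # 4!/(2!2!) orderings, only 3 distinct partitions: sampled p stays near exact
    assert res.p == pytest.approx(p_b, abs=0.05)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_permanova_statistic_matches_definition_on_random_inputs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 7))
    d = random_distance_matrix(n, rng)
    labels = [f"g{i % 2}" for i in range(n)]
    res = permanova(DistanceMatrix(d, [f"s{i}" for i in range(n)]), labels, 9, seed=0)
    f_b, r2_b = permanova_f_r2(d, labels)
    assert res.F == pytest.approx(f_b, rel=1e-10)
    assert res.R2 == pytest.approx(r2_b, rel=1e-10)


def test_permanova_r2_invariant_to_distance_scaling():
    rng = np.random.default_rng(8)
    d = random_distance_matrix(6, rng)
    labels = ["a", "a", "b", "b", "c", "c"]
    dm = DistanceMatrix(d, [f"s{i}" for i in range(6)])
    r1 = permanova(dm, labels, 49, seed=3)
    r2 = permanova(dm.with_values(3.7 * d), labels, 49, seed=3)
    assert r1.R2 == pytest.approx(r2.R2, rel=1e-12)
    assert r1.F == pytest.approx(r2.F, rel=1e-12)
    assert r1.p == r2.p


def test_permanova_agrees_with_skbio():
    """Independent cross-check of the pseudo-F against scikit-bio."""
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(4)
    d = random_distance_matrix(8, rng)
    labels = ["a"] * 3 + ["b"] * 2 + ["c"] * 3
    res = permanova(DistanceMatrix(d, [f"s{i}" for i in range(8)]), labels, 99, seed=0)
    sk = skbio_stats.permanova(
        skbio_stats.DistanceMatrix(d, [f"s{i}" for i in range(8)]),
        grouping=labels, permutations=99,
    )
    assert res.F == pytest.approx(float(sk["test statistic"]), rel=1e-10)


def test_permanova_p_is_valid_under_null():
    """Null calibration at small scale: rejection rate at alpha=0.05 over
    200 random-label datasets stays inside a generous binomial band."""
    rng = np.random.default_rng(77)
    rejections = 0
    n_sims = 200
    for i in range(n_sims):
        d = random_distance_matrix(9, rng)
        labels = rng.permutation(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res = permanova(
            DistanceMatrix(d, [f"s{k}" for k in range(9)]), labels, 99,
            seed=int(rng.integers(2**31 - 1)),
        )
        rejections += res.p <= 0.05
    rate = rejections / n_sims
    assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / n_sims) <= rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sims)


# ---- dispersion test ------------------------------------------------------


def test_dispersion_identical_geometry_not_rejected():
    # two groups with the same (isosceles) internal shape: dispersions are
    # exchangeable, so F is ~0 and the permutation p is ~1
    block = np.array([[0, 0.2, 0.3], [0.2, 0, 0.3], [0.3, 0.3, 0]])
    d = np.full((6, 6), 0.8)
    d[:3, :3] = block
    d[3:, 3:] = block
    np.fill_diagonal(d, 0.0)
    f, p = dispersion_test(
        DistanceMatrix(d, [f"s{i}" for i in range(6)]),
        ["a"] * 3 + ["b"] * 3, 199, seed=0,
    )
    assert f == pytest.approx(0.0, abs=1e-8)
    # exchangeable dispersions: far from rejection (ties at numerical zero
    # keep p below 1 but the test must not come close to alpha = 0.05)
    assert p > 0.3


def test_dispersion_detects_tight_vs_diffuse_groups():
    rng = np.random.default_rng(10)
    n_per = 10
    # Euclidean geometry: tight cloud (sd 0.05) vs diffuse cloud (sd 0.5)
    pts = np.vstack([
        rng.normal(0, 0.05, size=(n_per, 3)),
        rng.normal(5, 0.5, size=(n_per, 3)),
    ])
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    f, p = dispersion_test(
        DistanceMatrix(d, [f"s{i}" for i in range(2 * n_per)]),
        ["tight"] * n_per + ["diffuse"] * n_per, 499, seed=0,
    )
    assert p <= 0.05


def test_dispersion_embedding_matches_euclidean_centroids():
    """For genuinely Euclidean distances the PCoA centroid distances must
    equal the direct coordinate computation."""
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(7, 2))
    labels = np.array(["a", "a", "a", "b", "b", "b", "b"])
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    from dungdna.ecostats import _centroid_distances, _pcoa_axes

    real_axes, imag_axes = _pcoa_axes(DistanceMatrix(d, [f"s{i}" for i in range(7)]))
    _, codes = np.unique(labels, return_inverse=True)
    z = _centroid_distances(real_axes, imag_axes, codes)
    expected = np.empty(7)
    for g in ("a", "b"):
        idx = labels == g
        c = pts[idx].mean(axis=0)
        expected[idx] = np.sqrt(((pts[idx] - c) ** 2).sum(axis=1))
    np.testing.assert_allclose(z, expected, atol=1e-8)


def test_dispersion_rejects_coincident_samples():
    d = np.zeros((4, 4))
    with pytest.raises(ValidationError):
        dispersion_test(DistanceMatrix(d, list("abcd")), ["a", "a", "b", "b"], 9, seed=0)


# ---- transforms -----------------------------------------------------------


def test_inverse_normal_two_values():
    out = inverse_normal_transform(np.array([3.0, 7.0]))
    assert out[0] == pytest.approx(norm.ppf(0.25), abs=1e-12)
    assert out[1] == pytest.approx(norm.ppf(0.75), abs=1e-12)
    assert out[1] == pytest.approx(0.6744897, abs=1e-6)


def test_inverse_normal_is_monotone_and_handles_ties():
    rng = np.random.default_rng(12)
    v = rng.uniform(size=15)
    out = inverse_normal_transform(v)
    assert (np.argsort(out) == np.argsort(v)).all()
    tied = inverse_normal_transform(np.array([1.0, 2.0, 2.0, 5.0]))
    assert tied[1] == tied[2]
    const = inverse_normal_transform(np.array([4.0, 4.0, 4.0]))
    assert (const == 0).all()


def test_inverse_normal_distance_matrix_is_nonnegative_and_ordered():
    rng = np.random.default_rng(6)
    dm = DistanceMatrix(random_distance_matrix(6, rng), [f"s{i}" for i in range(6)])
    out = inverse_normal_distances(dm)
    assert out.transform == "inverse-normal"
    assert (out.condensed() >= 0).all()
    orig, trans = dm.condensed(), out.condensed()
    assert (np.argsort(orig) == np.argsort(trans)).all()


def test_cube_transform_fixed_points_and_tag():
    d = np.array([[0.0, 1.0], [1.0, 0.0]])
    out = cube_transform(DistanceMatrix(d, ["a", "b"]))
    np.testing.assert_allclose(out.values, d)
    assert out.transform == "cube-root"
    d2 = np.array([[0.0, 0.008], [0.008, 0.0]])
    out2 = cube_transform(DistanceMatrix(d2, ["a", "b"]))
    assert out2.values[0, 1] == pytest.approx(0.2)


# ---- UPGMA ----------------------------------------------------------------


def test_upgma_three_leaf_hand_case():
    # d(A,B)=2, d(A,C)=d(B,C)=4: merge (A,B) at height 1, then C at height 2
    d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    tree = upgma(DistanceMatrix(d, ["A", "B", "C"]))
    np.testing.assert_allclose(sorted(tree.merge_heights()), [1.0, 2.0])
    nwk = tree.to_newick()
    assert "A:1" in nwk and "B:1" in nwk and "C:2" in nwk


def test_upgma_two_leaves_newick_shape():
    d = np.array([[0.0, 0.6], [0.6, 0.0]])
    nwk = upgma(DistanceMatrix(d, ["A", "B"])).to_newick()
    assert nwk == "(A:0.3,B:0.3);"


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_upgma_matches_brute_force_oracle_up_to_8_leaves(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    d = random_distance_matrix(n, rng)
    tree = upgma(DistanceMatrix(d, [f"s{i}" for i in range(n)]))
    coph = cophenet(tree.merges)
    expected = brute_upgma_cophenetic(d)[np.triu_indices(n, k=1)]
    np.testing.assert_allclose(coph, expected, atol=1e-10)
    # ultrametric: merge heights non-decreasing
    heights = tree.merge_heights()
    assert (np.diff(heights) >= -1e-12).all()


# ---- richness ANOVA -------------------------------------------------------


def test_richness_anova_equal_means_small_f():
    f, p = richness_anova([5, 6, 7, 5, 6, 7], ["a", "a", "a", "b", "b", "b"])
    assert f == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_richness_anova_equals_squared_t_for_two_groups():
    rng = np.random.default_rng(2)
    x = rng.normal(10, 2, size=8)
    y = rng.normal(12, 2, size=6)
    f, p = richness_anova(
        np.concatenate([x, y]), ["a"] * 8 + ["b"] * 6
    )
    t_stat, t_p = ttest_ind(x, y)
    assert f == pytest.approx(t_stat**2, rel=1e-10)
    assert p == pytest.approx(t_p, rel=1e-10)


def test_richness_anova_hand_computed_three_by_three():
    vals = np.array([1.0, 2, 3, 2, 4, 6, 5, 6, 7])
    labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    grand = vals.mean()
    means = [vals[:3].mean(), vals[3:6].mean(), vals[6:].mean()]
    ssb = 3 * sum((m - grand) ** 2 for m in means)
    ssw = sum(((vals[i * 3:(i + 1) * 3] - means[i]) ** 2).sum() for i in range(3))
    f_expect = (ssb / 2) / (ssw / 6)
    f, _ = richness_anova(vals, labels)
    assert f == pytest.approx(f_expect, rel=1e-12)


# ---- trophic aggregation --------------------------------------------------


def test_trophic_union_semantics():
    pres = np.array([[1, 1, 0], [0, 0, 1]])
    cm = community(pres)
    mapping = {"t0": "Coleoptera A", "t1": "Coleoptera A", "t2": "Collembola"}
    out = trophic_aggregate(cm, mapping)
    # s0 has only dung-feeding beetles -> exactly one group present
    assert out.data.loc["s0"].sum() == 1
    assert out.data.loc["s0", "Coleoptera A"] == 1
    assert out.data.loc["s1", "Collembola"] == 1


def test_trophic_adding_taxon_never_removes_group():
    pres = np.array([[1, 0], [1, 0]])
    more = np.array([[1, 1], [1, 0]])
    mapping = {"t0": "Diptera D", "t1": "Acari"}
    a = trophic_aggregate(community(pres), mapping)
    b = trophic_aggregate(community(more), mapping)
    for g in a.data.columns:
        assert (b.data[g] >= a.data[g]).all()


def test_trophic_unmapped_taxa_fall_back_to_nonspecific():
    pres = np.array([[1, 1], [0, 1]])
    out = trophic_aggregate(community(pres), {"t0": "Diptera F"})
    assert set(out.data.columns) == {"Diptera F", "nonspecific"}
    assert out.data.loc["s1", "nonspecific"] == 1
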