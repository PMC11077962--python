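"""Diversity metrics against hand-computed and independent oracles."""

import io
import math

import numpy as np
import pandas as pd
import pytest
import skbio
from hypothesis import given, settings
from hypothesis import strategies as st

from wormbiome.core_io import AbundanceTable, DistanceMatrix, PhyloTree, ValidationError
from wormbiome.diversity import (
    alpha_diversity,
    alpha_diversity_table,
    anova_tukey,
    beta_diversity,
    clr_transform,
    diversity_trend,
    paired_distance_trend,
    pcoa,
    permanova,
)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts,metric,expected",
    [
        ([10, 10, 10, 10], "shannon", math.log(4)),
        ([10, 10, 10, 10], "simpson", 0.75),
        ([1, 1, 2, 5, 10], "chao1", 5.5),  # 5 + 2*1/(2*(1+1))
        ([7, 0, 0], "shannon", 0.0),
        ([5, 5], "simpson", 0.5),
    ],
)
def test_alpha_closed_forms(counts, metric, expected):
    assert alpha_diversity(counts, metric) == pytest.approx(expected, abs=1e-9)


def test_alpha_rejects_all_zero_and_unknown_metric():
    with pytest.raises(ValidationError):
        alpha_diversity([0, 0], "shannon")
    with pytest.raises(ValidationError):
        alpha_diversity([1, 2], "gini")


def test_chao1_at_least_observed_richness(small_table):
    frame = alpha_diversity_table(small_table, ["chao1"])
    obs = (small_table.counts > 0).sum(axis=1)
    assert np.all(frame["value"].to_numpy() >= obs - 1e-12)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


def _two_sample(x, y):
    return AbundanceTable.from_arrays(
        np.array([x, y]), ["a", "b"], [f"t{i}" for i in range(len(x))]
    )


def test_bray_curtis_hand_example():
    dm = beta_diversity(_two_sample([2, 2], [1, 3]), "bray_curtis")
    assert dm.pair("a", "b") == pytest.approx(0.25, abs=1e-9)


def test_aitchison_hand_example():
    # clr([e,1]) = [0.5,-0.5]; clr([1,e]) = [-0.5,0.5]; distance = sqrt(2)
    clr = clr_transform(np.array([[math.e, 1.0], [1.0, math.e]]), pseudocount=0.0)
    d = np.linalg.norm(clr[0] - clr[1])
    assert d == pytest.approx(math.sqrt(2), abs=1e-9)


def test_weighted_unifrac_two_leaf_extremes():
    tree = PhyloTree(skbio.TreeNode.read(io.StringIO("(A:1,B:1);")))
    t = AbundanceTable.from_arrays(
        np.array([[10, 0], [0, 10], [10, 0]]), ["s1", "s2", "s3"], ["A", "B"]
    )
    dm = beta_diversity(t, "weighted_unifrac", tree=tree)
    assert dm.pair("s1", "s2") == pytest.approx(1.0, abs=1e-9)
    assert dm.pair("s1", "s3") == pytest.approx(0.0, abs=1e-9)


def test_weighted_unifrac_requires_complete_tree(small_table):
    tree = PhyloTree(skbio.TreeNode.read(io.StringIO("(tA:1,tB:1);")))
    with pytest.raises(ValidationError, match="tC"):
        beta_diversity(small_table, "weighted_unifrac", tree=tree)
    with pytest.raises(ValidationError, match="tree"):
        beta_diversity(small_table, "weighted_unifrac", tree=None)


def test_weighted_unifrac_matches_brute_force_branch_sum():
    """Normalized weighted UniFrac vs per-branch summation on random trees."""
    from wormbiome.simulate import random_tree

    rng = np.random.default_rng(42)
    for rep in range(100):
        taxa = [f"L{i}" for i in range(6)]
        tree = random_tree(taxa, rep)
        counts = rng.integers(0, 50, size=(2, 6))
        counts[:, 0] += 1  # avoid empty samples
        tb = AbundanceTable.from_arrays(counts, ["a", "b"], taxa)
        dm = beta_diversity(tb, "weighted_unifrac", tree=tree)
        idx = {t: i for i, t in enumerate(taxa)}
        px = counts[0] / counts[0].sum()
        py = counts[1] / counts[1].sum()
        num = den = 0.0
        for node in tree.tree.traverse(include_self=False):
            tips = [t.name for t in node.tips()] or [node.name]
            pa = sum(px[idx[t]] for t in tips)
            pb = sum(py[idx[t]] for t in tips)
            num += node.length * abs(pa - pb)
            den += node.length * (pa + pb)
        assert dm.pair("a", "b") == pytest.approx(num / den, abs=1e-10)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10**6))
def test_distance_axioms_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 30, size=(4, 6))
    counts[:, 0] += 1
    t = AbundanceTable.from_arrays(
        counts, [f"s{i}" for i in range(4)], [f"t{i}" for i in range(6)]
    )
    for metric in ("bray_curtis", "aitchison"):
        dm = beta_diversity(t, metric)
        v = dm.values
        assert np.all(np.diag(v) == 0)
        assert np.all(v >= 0)
        assert np.allclose(v, v.T, atol=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10**6), st.floats(0.1, 100.0))
def test_aitchison_scale_invariance(seed, c):
    rng = np.random.default_rng(seed)
    x = rng.integers(1, 50, size=8).astype(float)
    clr_a = clr_transform(x, pseudocount=0.0)
    clr_b = clr_transform(c * x, pseudocount=0.0)
    assert np.linalg.norm(clr_a - clr_b) == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


def test_pcoa_two_point_hand_example():
    D = DistanceMatrix(("a", "b"), np.array([[0.0, 2.0], [2.0, 0.0]]), "toy")
    res = pcoa(D, 1)
    coords = res.coordinates.to_numpy().ravel()
    assert sorted(np.round(coords, 9)) == [-1.0, 1.0]
    assert res.eigenvalues[0] == pytest.approx(2.0, abs=1e-9)


def test_pcoa_recovers_euclidean_configuration():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(6, 2))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    D = DistanceMatrix(tuple(f"s{i}" for i in range(6)), d, "euclid")
    res = pcoa(D, 5)
    rec = res.coordinates.to_numpy()
    d_rec = np.linalg.norm(rec[:, None] - rec[None, :], axis=-1)
    assert np.allclose(d_rec, d, atol=1e-9)


def test_pcoa_identical_samples_all_zero():
    D = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)), "toy")
    res = pcoa(D, 2)
    assert np.allclose(res.coordinates.to_numpy(), 0.0)


def test_pcoa_matches_skbio():
    rng = np.random.default_rng(1)
    counts = rng.integers(1, 40, size=(7, 5))
    t = AbundanceTable.from_arrays(
        counts, [f"s{i}" for i in range(7)], [f"t{i}" for i in range(5)]
    )
    dm = beta_diversity(t, "bray_curtis")
    ours = pcoa(dm, 3)
    theirs = skbio.stats.ordination.pcoa(dm.to_skbio())
    assert np.allclose(
        ours.eigenvalues[:3], theirs.eigvals.to_numpy()[:3], atol=1e-8
    )
    for k in range(3):
        a = ours.coordinates.iloc[:, k].to_numpy()
        b = theirs.samples.iloc[:, k].to_numpy()
        assert np.allclose(np.abs(a), np.abs(b), atol=1e-6)  # sign-free


def test_pcoa_bad_k(small_table):
    dm = beta_diversity(small_table, "bray_curtis")
    with pytest.raises(ValidationError):
        pcoa(dm, 0)
    with pytest.raises(ValidationError):
        pcoa(dm, 4)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _line_distance_matrix():
    pts = np.array([0.0, 1.0, 10.0, 11.0])
    d = np.abs(pts[:, None] - pts[None, :])
    return DistanceMatrix(("s1", "s2", "s3", "s4"), d, "euclid")


def test_permanova_hand_example_f_and_exhaustive_p():
    res = permanova(_line_distance_matrix(), ["g1", "g1", "g2", "g2"], n_perm=999)
    assert res.pseudo_f == pytest.approx(200.0, abs=1e-9)
    assert res.exhaustive
    assert res.p_value == pytest.approx(1.0 / 3.0, abs=1e-12)


def test_permanova_matches_skbio_pseudo_f():
    rng = np.random.default_rng(3)
    counts = rng.integers(1, 40, size=(9, 6))
    t = AbundanceTable.from_arrays(
        counts, [f"s{i}" for i in range(9)], [f"t{i}" for i in range(6)]
    )
    dm = beta_diversity(t, "bray_curtis")
    groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    ours = permanova(dm, groups, n_perm=99, seed=0)
    theirs = skbio.stats.distance.permanova(dm.to_skbio(), grouping=groups, permutations=0)
    assert ours.pseudo_f == pytest.approx(theirs["test statistic"], abs=1e-9)


def test_permanova_group_size_validation():
    D = DistanceMatrix(("a", "b", "c"), np.ones((3, 3)) - np.eye(3), "toy")
    with pytest.raises(ValidationError):
        permanova(D, ["g1", "g1", "g2"])
    with pytest.raises(ValidationError):
        permanova(D, ["g1", "g1", "g1"])


# ---------------------------------------------------------------------------
# paired distance trends
# ---------------------------------------------------------------------------


def test_paired_trend_identical_communities_mean_zero(small_metadata):
    v = np.zeros((4, 4))
    D = DistanceMatrix(("s1", "s2", "s3", "s4"), v, "toy")
    out = paired_distance_trend(D, small_metadata, ("host", "control"), "random", 10, 0)
    assert np.allclose(out["mean"], 0.0)


def test_paired_trend_single_pair_modes_agree():
    md = pd.DataFrame(
        {
            "source": ["host", "substrate"],
            "time_h": [16.0, 16.0],
            "replicate": ["r1", "r1"],
            "plate": ["p1", "p1"],
        },
        index=["h1", "u1"],
    )
    from wormbiome.core_io import SampleMetadata

    meta = SampleMetadata(md)
    D = DistanceMatrix(("h1", "u1"), np.array([[0.0, 0.7], [0.7, 0.0]]), "toy")
    a = paired_distance_trend(D, meta, ("host", "substrate"), "plate")
    b = paired_distance_trend(D, meta, ("host", "substrate"), "random", n_rep=100)
    assert a["mean"].iloc[0] == pytest.approx(b["mean"].iloc[0], abs=1e-12)


# ---------------------------------------------------------------------------
# trends and ANOVA
# ---------------------------------------------------------------------------


def test_spearman_monotone_and_reversed():
    assert diversity_trend([0.1, 0.2, 0.3], [1, 2, 3]).rho == pytest.approx(1.0)
    assert diversity_trend([0.3, 0.2, 0.1], [1, 2, 3]).rho == pytest.approx(-1.0)


def test_spearman_midrank_ties():
    res = diversity_trend([1, 1, 2], [1, 2, 3])
    assert res.rho == pytest.approx(np.sqrt(3) / 2, abs=1e-9)


def test_spearman_constant_values_flagged():
    res = diversity_trend([2, 2, 2], [1, 2, 3])
    assert res.constant and res.rho == 0.0


def test_anova_hand_example_and_null():
    anova, _ = anova_tukey([0, 1, 2, 3], ["g1", "g1", "g2", "g2"])
    assert anova.loc["C(a)", "F"] == pytest.approx(8.0, abs=1e-9)
    assert anova.loc["C(a)", "df"] == 1 and anova.loc["Residual", "df"] == 2
    anova0, _ = anova_tukey([1, 3, 1, 3], ["g1", "g1", "g2", "g2"])
    assert anova0.loc["C(a)", "F"] == pytest.approx(0.0, abs=1e-12)


def test_tukey_two_groups_equals_anova_p():
    anova, tukey = anova_tukey([0.3, 1.1, 2.2, 3.1, 0.5, 2.9], ["a", "a", "b", "b", "a", "b"])
    assert tukey["p_adj"].iloc[0] == pytest.approx(anova.loc["C(a)", "PR(>F)"], abs=1e-9)


def test_anova_two_way_has_both_factors():
    rng = np.random.default_rng(0)
    v = rng.normal(size=12)
    fa = ["x", "y"] * 6
    fb = ["t1"] * 6 + ["t2"] * 6
    anova, _ = anova_tukey(v, fa, fb)
    assert "C(a)" in anova.index and "C(b)" in anova.index


def test_anova_small_level_rejected():
    with pytest.raises(ValidationError):
        anova_tukey([1, 2, 3], ["a", "a", "b"])
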