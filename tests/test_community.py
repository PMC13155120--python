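"""Abundance normalization, community-weighted traits, Hill numbers, PCoA."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from giftdistill.community import (
    RelativeAbundance,
    community_weighted_gifts,
    diversity_table,
    filter_by_coverage,
    hill_functional_q1,
    hill_neutral_q1,
    hill_phylo_q1,
    pcoa,
    percent_mapped,
    relative_abundance,
    rpmm,
    trait_distance,
)
from giftdistill.errors import DegenerateDataError, InputError

from conftest import make_abundance


# ---------------------------------------------------------------- filtering
def test_coverage_filter_is_cellwise_and_strict():
    table = make_abundance([[100, 100], [100, 100]], breadth=[[0.29, 0.30], [1.0, 0.0]])
    kept = filter_by_coverage(table, 0.30)
    assert kept.counts.iloc[0, 0] == 0  # 0.29 < 0.30 -> zeroed
    assert kept.counts.iloc[0, 1] == 100  # exactly 0.30 retained
    assert kept.counts.iloc[1, 0] == 100
    assert kept.counts.iloc[1, 1] == 0


def test_full_breadth_table_is_unchanged_and_filter_never_increases():
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 5000, size=(6, 4))
    full = make_abundance(counts)
    assert filter_by_coverage(full).counts.equals(full.counts)
    partial = make_abundance(counts, breadth=rng.random((6, 4)))
    kept = filter_by_coverage(partial)
    assert (kept.counts.values <= partial.counts.values).all()
    assert (percent_mapped(kept) <= percent_mapped(partial) + 1e-12).all()


def test_coverage_threshold_validated():
    table = make_abundance([[1]])
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(InputError):
            filter_by_coverage(table, bad)


# ------------------------------------------------------------ percent mapped
def test_percent_mapped_worked_examples():
    table = make_abundance([[5_000_000]], total=[10_000_000], mapped=[5_000_000])
    assert percent_mapped(table).iloc[0] == pytest.approx(50.0)
    none = make_abundance([[0]], total=[10], mapped=[0])
    assert percent_mapped(none).iloc[0] == 0.0
    all_mapped = make_abundance([[10]], total=[10], mapped=[10])
    assert percent_mapped(all_mapped).iloc[0] == pytest.approx(100.0)


# ----------------------------------------------------------------------- rpmm
def test_rpmm_worked_example_and_zero_counts():
    table = make_abundance(
        [[1000], [0]], lengths=[2_000_000, 1_000_000], total=[20_000_000], mapped=[10_000_000]
    )
    out = rpmm(table)
    assert out.iloc[0, 0] == pytest.approx(50.0)  # 1000 / 2 / 10
    assert out.iloc[1, 0] == 0.0


def test_rpmm_scale_invariance_and_relative_abundance_invariance():
    counts = np.array([[1200, 300], [40, 900], [0, 77]])
    base = make_abundance(counts, lengths=[1e6, 2e6, 3e6])
    doubled = make_abundance(counts * 2, lengths=[1e6, 2e6, 3e6])
    np.testing.assert_allclose(rpmm(base).values, rpmm(doubled).values, rtol=1e-12)
    np.testing.assert_allclose(
        relative_abundance(base).values.values,
        relative_abundance(doubled).values.values,
        rtol=1e-12,
    )


def test_rpmm_flags_unmapped_samples_as_missing():
    table = make_abundance([[0], [0]], total=[10], mapped=[0])
    with pytest.warns(UserWarning, match="no mapped reads"):
        out = rpmm(table)
    assert out.isna().all().all()


def test_relative_abundance_length_standardization():
    table = make_abundance([[100], [100]], lengths=[1_000_000, 2_000_000])
    rel = relative_abundance(table)
    np.testing.assert_allclose(rel.values.iloc[:, 0], [2 / 3, 1 / 3])
    single = relative_abundance(make_abundance([[42]]))
    assert single.values.iloc[0, 0] == 1.0


def test_relative_abundance_columns_sum_to_one_or_flag_empty():
    table = make_abundance([[10, 0], [5, 0]], total=[100, 100], mapped=[15, 0])
    with pytest.warns(UserWarning, match="empty"):
        rel = relative_abundance(table)
    assert rel.empty_samples == ("s2",)
    assert rel.values["s1"].sum() == pytest.approx(1.0, abs=1e-9)


# ------------------------------------------------------ community-weighted
def _rel(values, genomes, samples=("s1",)):
    df = pd.DataFrame(values, index=pd.Index(genomes, name="genome"), columns=list(samples))
    return RelativeAbundance(df)


def test_community_weighted_gifts_is_abundance_weighted_mean():
    gifts = pd.DataFrame(
        {"B1": [0.1, 0.3], "B2": [0.1, 0.3]}, index=pd.Index(["g1", "g2"], name="genome")
    )
    prof = community_weighted_gifts(_rel([[0.5], [0.5]], ["g1", "g2"]), gifts)
    assert prof.cw_gifts.loc["s1", "B1"] == pytest.approx(0.2)
    assert prof.community_mci.loc["s1"] == pytest.approx(0.2)

    solo = community_weighted_gifts(_rel([[1.0], [0.0]], ["g1", "g2"]), gifts)
    np.testing.assert_allclose(solo.cw_gifts.loc["s1"], gifts.loc["g1"])


def test_community_mci_is_a_convex_combination():
    rng = np.random.default_rng(3)
    gifts = pd.DataFrame(
        rng.random((5, 4)), index=pd.Index([f"g{i}" for i in range(5)], name="genome")
    )
    member_mci = gifts.mean(axis=1)
    for _ in range(20):
        p = rng.dirichlet(np.ones(5))
        prof = community_weighted_gifts(_rel(p[:, None], gifts.index), gifts)
        v = prof.community_mci.iloc[0]
        assert member_mci.min() - 1e-12 <= v <= member_mci.max() + 1e-12
    # a uniform trait value is preserved under any weighting
    flat = community_weighted_gifts(_rel(p[:, None], gifts.index), gifts * 0 + 0.37)
    assert flat.cw_gifts.iloc[0, 0] == pytest.approx(0.37)


def test_community_weighted_gifts_requires_aligned_genomes():
    gifts = pd.DataFrame({"B1": [0.1]}, index=pd.Index(["gX"], name="genome"))
    with pytest.raises(InputError):
        community_weighted_gifts(_rel([[1.0]], ["gY"]), gifts)


# ------------------------------------------------------------- Hill numbers
def test_neutral_hill_examples():
    assert hill_neutral_q1(np.array([0.5, 0.5])) == pytest.approx(2.0)
    assert hill_neutral_q1(np.array([1.0, 0.0])) == pytest.approx(1.0)
    # exp of hand-computed Shannon entropy of (0.7, 0.2, 0.1)
    assert hill_neutral_q1(np.array([0.7, 0.2, 0.1])) == pytest.approx(2.22967, abs=1e-4)
    with pytest.raises(InputError):
        hill_neutral_q1(np.array([-0.1, 1.1]))


def test_neutral_hill_bounded_by_richness_with_equality_at_uniform():
    rng = np.random.default_rng(8)
    for _ in range(50):
        s = int(rng.integers(2, 12))
        p = rng.dirichlet(np.ones(s))
        assert hill_neutral_q1(p) <= s + 1e-9
    assert hill_neutral_q1(np.full(7, 1 / 7)) == pytest.approx(7.0)


def test_phylo_hill_star_tree_reduces_to_neutral():
    star = TreeNode.read(["(a:1,b:1):0;"])
    p = pd.Series({"a": 0.5, "b": 0.5})
    assert hill_phylo_q1(p, star) == pytest.approx(2.0)
    assert hill_phylo_q1(pd.Series({"a": 1.0, "b": 0.0}), star) == pytest.approx(1.0)


def test_phylo_hill_matches_branch_enumeration_oracle():
    # comb tree ((a:1,b:1):1,c:2); with p = (0.5, 0.3, 0.2)
    tree = TreeNode.read(["((a:1,b:1):1,c:2);"])
    p = pd.Series({"a": 0.5, "b": 0.3, "c": 0.2})
    # independent oracle: branches listed by hand as (length, tip abundance sum)
    branches = [(1.0, 0.5), (1.0, 0.3), (1.0, 0.8), (2.0, 0.2)]
    T = sum(L * a for L, a in branches)
    expected = np.exp(-sum(L / T * a * np.log(a) for L, a in branches))
    assert hill_phylo_q1(p, tree) == pytest.approx(expected, abs=1e-12)


def test_phylo_hill_requires_taxa_on_tree():
    tree = TreeNode.read(["(a:1,b:1):0;"])
    with pytest.raises(InputError, match="missing"):
        hill_phylo_q1(pd.Series({"a": 0.5, "z": 0.5}), tree)


def test_functional_hill_examples_and_invariance():
    d = np.array([[0.0, 1.0], [1.0, 0.0]])
    p = np.array([0.5, 0.5])
    assert hill_functional_q1(p, d) == pytest.approx(4.0)
    assert hill_functional_q1(p, d * 17.3) == pytest.approx(4.0)  # d/Q invariance
    with pytest.raises(DegenerateDataError):
        hill_functional_q1(np.array([1.0]), np.zeros((1, 1)))
    with pytest.raises(InputError):
        hill_functional_q1(p, np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric


# ---------------------------------------------------------------------- PCoA
def test_pcoa_recovers_collinear_geometry():
    pts = np.array([[0.0], [1.0], [3.0]])
    d = np.abs(pts - pts.T)
    coords, eigvals = pcoa(d)
    assert (eigvals > 1e-9).sum() == 1
    got = np.sort(np.abs(coords.values[:, 0] - coords.values[0, 0]))
    np.testing.assert_allclose(np.sort(d[0]), got, atol=1e-9)


def test_pcoa_reconstructs_euclidean_distances():
    rng = np.random.default_rng(2)
    gifts = pd.DataFrame(
        rng.random((8, 5)), index=pd.Index([f"g{i}" for i in range(8)], name="genome")
    )
    d = trait_distance(gifts)
    coords, eigvals = pcoa(d)
    assert (eigvals < -1e-8).sum() == 0  # Euclidean input: no negative axes
    from scipy.spatial.distance import pdist, squareform

    recon = squareform(pdist(coords.values))
    np.testing.assert_allclose(recon, d.values, atol=1e-8)


def test_pcoa_matches_scikit_bio_reference():
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.ordination import pcoa as skbio_pcoa

    rng = np.random.default_rng(4)
    x = rng.random((7, 3))
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(x))
    coords, eigvals = pcoa(d)
    ref = skbio_pcoa(DistanceMatrix(d), method="eigh")
    np.testing.assert_allclose(
        np.sort(eigvals.values[eigvals.values > 1e-10]),
        np.sort(ref.eigvals.values[ref.eigvals.values > 1e-10]),
        rtol=1e-8,
    )
    np.testing.assert_allclose(
        np.abs(coords.values[:, 0]), np.abs(ref.samples.values[:, 0]), atol=1e-8
    )


def test_pcoa_degenerate_and_invalid_inputs():
    coords, eigvals = pcoa(np.zeros((3, 3)))
    assert coords.shape[1] == 0  # identical rows -> no positive axes
    with pytest.raises(InputError):
        pcoa(np.zeros((2, 3)))


# ---------------------------------------------------------- diversity table
def test_diversity_table_star_tree_agrees_with_neutral():
    rng = np.random.default_rng(9)
    names = [f"g{i}" for i in range(6)]
    star = TreeNode.read(["(" + ",".join(f"{n}:1" for n in names[:-1]) + f",{names[-1]}:1):0;"])
    p = rng.dirichlet(np.ones(6), size=3).T
    rel = RelativeAbundance(
        pd.DataFrame(p, index=pd.Index(names, name="genome"), columns=["s1", "s2", "s3"])
    )
    gifts = pd.DataFrame(rng.random((6, 4)), index=rel.values.index)
    out = diversity_table(rel, tree=star, traits=gifts)
    np.testing.assert_allclose(out["neutral"], out["phylogenetic"], atol=1e-9)
    assert (out["functional"] > 0).all()
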