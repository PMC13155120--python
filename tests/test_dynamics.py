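"""Bootstrap-support responses, correlations, correlogram, group comparisons."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from giftdistill.dynamics import (
    bootstrap_mean_ci,
    classify_community,
    group_compare_bootstrap,
    mci_response_correlation,
    phylo_correlogram,
    prevalent_taxa,
    taxon_response,
    taxon_responses,
)
from giftdistill.errors import InputError
from giftdistill.synthetic import brownian_tips, simulate_tree


def _series(values, prefix="s"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


def test_noise_free_proportional_abundance_has_full_support():
    x = _series(np.linspace(1, 10, 20))
    resp = taxon_response(np.expm1(0.3 * x), x, n_boot=200, seed=1)
    assert resp.support == 1.0
    assert resp.direction == "increase"
    assert resp.slope == pytest.approx(0.3, rel=1e-6)


def test_support_is_invariant_to_affine_predictor_rescaling():
    rng = np.random.default_rng(0)
    x = _series(rng.normal(size=30))
    y = pd.Series(np.exp(0.4 * x + rng.normal(0, 0.5, 30)), index=x.index)
    a = taxon_response(y, x, n_boot=300, seed=5)
    b = taxon_response(y, 100 + 7 * x, n_boot=300, seed=5)
    c = taxon_response(y, -x, n_boot=300, seed=5)
    assert a.support == b.support == c.support
    assert a.direction == b.direction
    assert c.direction == ("decrease" if a.direction == "increase" else a.direction)


def test_response_preconditions():
    x = _series(np.arange(6.0))
    with pytest.raises(InputError, match="8 samples"):
        taxon_response(x, x, n_boot=10, seed=0)
    const = _series(np.ones(10))
    with pytest.raises(InputError, match="constant"):
        taxon_response(const, const, n_boot=10, seed=0)


def test_null_taxa_are_mostly_unclassified():
    """Under independence the sign support is ~Uniform(0.5, 1), so the
    expected unclassified fraction at the 0.9 threshold is 0.80."""
    rng = np.random.default_rng(12)
    n, taxa = 60, 300
    x = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
    Y = pd.DataFrame(
        rng.lognormal(0, 1, size=(taxa, n)),
        index=[f"t{i}" for i in range(taxa)],
        columns=x.index,
    )
    resp = taxon_responses(Y, x, n_boot=400, seed=3)
    frac = classify_community(resp)
    assert 0.72 <= frac["none"] <= 0.90


def test_batch_and_single_taxon_agree_on_point_estimates():
    rng = np.random.default_rng(7)
    x = pd.Series(rng.normal(size=25), index=[f"s{i}" for i in range(25)])
    Y = pd.DataFrame(
        rng.lognormal(0, 1, size=(4, 25)), index=list("abcd"), columns=x.index
    )
    batch = taxon_responses(Y, x, n_boot=50, seed=2)
    for taxon in Y.index:
        single = taxon_response(Y.loc[taxon], x, n_boot=50, seed=2)
        assert single.slope == pytest.approx(batch.loc[taxon, "slope"], rel=1e-9)


def test_bootstrap_results_are_reproducible_under_seed():
    rng = np.random.default_rng(21)
    x = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
    Y = pd.DataFrame(rng.lognormal(0, 1, size=(5, 30)), index=list("abcde"), columns=x.index)
    a = taxon_responses(Y, x, n_boot=100, seed=9)
    b = taxon_responses(Y, x, n_boot=100, seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_classify_community_fractions():
    df = pd.DataFrame({"direction": ["increase"] * 3})
    assert classify_community(df) == {"increase": 1.0, "decrease": 0.0, "none": 0.0}
    df = pd.DataFrame({"direction": ["none", "none"]})
    assert classify_community(df)["none"] == 1.0
    mixed = classify_community(pd.DataFrame({"direction": ["increase", "decrease", "none", "none"]}))
    assert sum(mixed.values()) == pytest.approx(1.0)
    with pytest.raises(InputError):
        classify_community(pd.DataFrame({"direction": []}))


def test_prevalent_taxa_threshold():
    df = pd.DataFrame([[0, 0, 0, 1], [1, 1, 0, 0], [1, 1, 1, 1]], index=list("abc"))
    assert list(prevalent_taxa(df, 0.5)) == ["b", "c"]
    assert list(prevalent_taxa(df, 0.0)) == ["a", "b", "c"]


# ------------------------------------------------------------- correlation
def test_exact_negative_relation_gives_r_minus_one():
    mci = pd.Series(np.linspace(0.1, 0.9, 20), index=[f"g{i}" for i in range(20)])
    r, p = mci_response_correlation(mci, -mci, n_perm=499, seed=0)
    assert r == pytest.approx(-1.0)
    assert p <= 0.01


def test_independent_vectors_rarely_look_correlated():
    hits = 0
    for seed in range(12):
        rng = np.random.default_rng(seed)
        mci = pd.Series(rng.random(150), index=[f"g{i}" for i in range(150)])
        slopes = pd.Series(rng.normal(size=150), index=mci.index)
        r, _ = mci_response_correlation(mci, slopes, n_perm=99, seed=seed)
        hits += abs(r) < 0.3
    assert hits >= 11  # |r| < 0.3 in >= ~95% of seeds at n = 150


def test_correlation_preconditions():
    idx = [f"g{i}" for i in range(10)]
    flat = pd.Series(np.ones(10), index=idx)
    var = pd.Series(np.arange(10.0), index=idx)
    with pytest.raises(InputError, match="variance"):
        mci_response_correlation(flat, var)
    with pytest.raises(InputError):
        mci_response_correlation(var.iloc[:3], var.iloc[:3])


# -------------------------------------------------------------- correlogram
def test_two_tip_tree_has_one_defined_class():
    tree = TreeNode.read(["(a:1,b:1):0;"])
    out = phylo_correlogram(pd.Series({"a": 1.0, "b": -1.0}), tree, n_classes=1)
    assert len(out) == 1
    assert out["moran_i"].iloc[0] == pytest.approx(-1.0)
    assert out["null_expectation"].iloc[0] == pytest.approx(-1.0)


def test_brownian_responses_are_autocorrelated_at_short_distances():
    hits = 0
    for seed in range(8):
        newick = simulate_tree(40, seed=seed)
        tree = TreeNode.read([newick])
        trait = brownian_tips(tree, sigma=1.0, rng=np.random.default_rng(seed + 100))
        out = phylo_correlogram(trait, tree, n_classes=5)
        hits += out["moran_i"].iloc[0] > 0
    assert hits >= 7


def test_permuted_responses_center_on_the_moran_null():
    newick = simulate_tree(30, seed=3)
    tree = TreeNode.read([newick])
    rng = np.random.default_rng(0)
    trait = brownian_tips(tree, sigma=1.0, rng=rng)
    first_class = []
    for _ in range(200):
        shuffled = pd.Series(rng.permutation(trait.values), index=trait.index)
        first_class.append(phylo_correlogram(shuffled, tree, n_classes=3)["moran_i"].iloc[0])
    assert np.mean(first_class) == pytest.approx(-1 / 29, abs=0.02)


def test_correlogram_class_count_validated():
    tree = TreeNode.read(["(a:1,b:1):0;"])
    with pytest.raises(InputError):
        phylo_correlogram(pd.Series({"a": 1.0, "b": 2.0}), tree, n_classes=5)


# -------------------------------------------------------- group comparison
def test_identical_groups_overlap_and_constant_groups_collapse():
    values = pd.Series([5.0] * 6, index=list("abcdef"))
    groups = pd.Series(["x"] * 3 + ["y"] * 3, index=values.index)
    out = group_compare_bootstrap(values, groups, n_boot=500, seed=0)
    assert out.verdicts[("x", "y")] == "overlapping"
    assert out.table.loc["x", "ci_low"] == out.table.loc["x", "ci_high"] == 5.0


def test_separated_groups_are_distinct():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        values = pd.Series(
            np.concatenate([rng.normal(0, 1, 30), rng.normal(3, 1, 30)]),
            index=[f"t{i}" for i in range(60)],
        )
        groups = pd.Series(["a"] * 30 + ["b"] * 30, index=values.index)
        out = group_compare_bootstrap(values, groups, n_boot=1000, seed=seed)
        hits += out.verdicts[("a", "b")] == "distinct"
    assert hits == 10


def test_ci_contains_mean_and_widens_with_level():
    rng = np.random.default_rng(1)
    values = rng.normal(size=40)
    mean, lo90, hi90 = bootstrap_mean_ci(values, n_boot=2000, level=0.90, rng=np.random.default_rng(2))
    mean2, lo99, hi99 = bootstrap_mean_ci(values, n_boot=2000, level=0.99, rng=np.random.default_rng(2))
    assert lo90 <= mean <= hi90
    assert lo99 <= lo90 and hi99 >= hi90


def test_singleton_group_rejected():
    values = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
    groups = pd.Series(["x", "x", "y"], index=values.index)
    with pytest.raises(InputError, match="fewer than 2"):
        group_compare_bootstrap(values, groups, n_boot=10, seed=0)
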