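"""Proportionality dissimilarity, Ward linkage oracle, KGS cut choice."""

import numpy as np
import pandas as pd
import pytest

import crcmicro as cm
from oracles import naive_ward, scipy_linkage_merges
from crcmicro.cluster import LinkageResult
from crcmicro.errors import DegenerateTaxonError, ValidationError


def _counts_from_log(logs, depth=100_000):
    """Build integer counts whose CLR values mirror the given logs."""
    p = np.exp(logs)
    p = p / p.sum(axis=1, keepdims=True)
    counts = np.floor(p * depth).astype(int) + 1
    return cm.FeatureTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(logs.shape[0])],
        columns=[f"t{j}" for j in range(logs.shape[1])]))


# ---------------------------------------------------------------------------
# proportionality
# ---------------------------------------------------------------------------

def test_duplicated_taxon_dissimilarity_zero():
    rng = np.random.default_rng(0)
    logs = rng.normal(5, 1, size=(100, 4))
    logs[:, 1] = logs[:, 0]                      # duplicate on log scale
    table = _counts_from_log(logs, depth=10**7)
    d = cm.proportionality_dissimilarity(table)
    assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-3)


def test_proportional_pair_rho_one():
    """y = 2x on the natural scale is log-shifted, hence rho = 1."""
    rng = np.random.default_rng(1)
    logs = rng.normal(3, 1, size=(200, 5))
    logs[:, 1] = logs[:, 0] + np.log(2)
    table = _counts_from_log(logs, depth=10**7)
    d = cm.proportionality_dissimilarity(table)
    assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-3)


def test_independent_taxa_rho_near_zero():
    rng = np.random.default_rng(2)
    logs = rng.normal(4, 1, size=(500, 20))
    table = _counts_from_log(logs, depth=10**7)
    d = cm.proportionality_dissimilarity(table)
    rho01 = 1 - d.iloc[0, 1]
    assert abs(rho01) < 0.15


def test_zero_variance_taxon_rejected():
    # identical rows make every CLR series constant -> zero variance
    counts = pd.DataFrame({"t0": [5, 5, 5], "t1": [2, 2, 2]},
                          index=["a", "b", "c"])
    with pytest.raises(DegenerateTaxonError):
        cm.proportionality_dissimilarity(cm.FeatureTable(counts))


# ---------------------------------------------------------------------------
# Ward linkage vs naive O(n^3) oracle
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n", [5, 8, 12])
def test_ward_merge_sequence_matches_oracle(n):
    rng = np.random.default_rng(n)
    pts = rng.normal(size=(n, 3))
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(pts))
    labels = [f"t{i:02d}" for i in range(n)]
    result = cm.ward_cluster(pd.DataFrame(d, index=labels, columns=labels))
    ours = scipy_linkage_merges(result)
    oracle = naive_ward(d)
    for (la, ha), (lb, hb) in zip(ours, oracle):
        assert la == lb
        assert ha == pytest.approx(hb, rel=1e-10)


def test_two_taxa_single_merge():
    d = pd.DataFrame([[0, 0.8], [0.8, 0]], index=["a", "b"],
                     columns=["a", "b"])
    result = cm.ward_cluster(d)
    assert result.linkage.shape == (1, 4)
    assert result.linkage[0, 2] == pytest.approx(0.8)


def test_ward_invariant_to_taxon_order():
    rng = np.random.default_rng(9)
    pts = rng.normal(size=(8, 3))
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(pts))
    labels = [f"t{i}" for i in range(8)]
    df = pd.DataFrame(d, index=labels, columns=labels)
    shuffled = df.iloc[::-1, ::-1]
    a = scipy_linkage_merges(cm.ward_cluster(df))
    b = scipy_linkage_merges(cm.ward_cluster(shuffled))
    # leaf indices refer to the sorted label order, so sequences match
    assert [(x[0], pytest.approx(x[1])) for x in a] == b


def test_ward_nan_rejected():
    d = pd.DataFrame([[0, np.nan], [np.nan, 0]], index=["a", "b"],
                     columns=["a", "b"])
    with pytest.raises(ValidationError):
        cm.ward_cluster(d)


def test_first_merges_within_planted_blocks():
    rng = np.random.default_rng(12)
    blocks = []
    for center in (0.0, 6.0, 12.0):
        blocks.append(rng.normal(center, 0.2, size=(4, 2)))
    pts = np.vstack(blocks)
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(pts))
    labels = [f"t{i:02d}" for i in range(12)]
    result = cm.ward_cluster(pd.DataFrame(d, index=labels, columns=labels))
    merges = scipy_linkage_merges(result)
    true_block = np.repeat([0, 1, 2], 4)
    for leaves, _ in merges[:6]:     # early merges stay within one block
        assert len({true_block[leaf] for leaf in leaves}) == 1


# ---------------------------------------------------------------------------
# KGS penalty
# ---------------------------------------------------------------------------

def _block_dissimilarity(rng, sizes, within=0.2, between=1.5):
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.where(labels[:, None] == labels[None, :], within, between)
    d = d + rng.uniform(0, 0.02, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    names = [f"t{i:02d}" for i in range(n)]
    return pd.DataFrame(d, index=names, columns=names)


def test_kgs_recovers_three_blocks():
    rng = np.random.default_rng(21)
    d = _block_dissimilarity(rng, [5, 6, 7])
    tree = cm.ward_cluster(d)
    assert cm.kgs_optimal_k(tree, d) == 3


def test_kgs_degenerate_blob_returns_two():
    """A blob of near-identical items has a flat spread profile; the
    tie rule yields the smallest cut, k=2."""
    n = 15
    d = np.zeros((n, n))
    names = [f"t{i:02d}" for i in range(n)]
    d = pd.DataFrame(d, index=names, columns=names)
    tree = cm.ward_cluster(d)
    with pytest.warns(UserWarning):
        assert cm.kgs_optimal_k(tree, d) == 2


def test_kgs_prefers_block_count_over_finer_cuts():
    """With genuine block structure the penalty's knee sits at the true
    block count, not at a finer cut."""
    rng = np.random.default_rng(22)
    d = _block_dissimilarity(rng, [6, 6, 6, 6])
    tree = cm.ward_cluster(d)
    assert cm.kgs_optimal_k(tree, d) == 4


def test_kgs_three_equidistant_leaves_tie_gives_two():
    d = pd.DataFrame(
        np.array([[0, 1.0, 1.0], [1.0, 0, 1.0], [1.0, 1.0, 0]]),
        index=list("abc"), columns=list("abc"))
    tree = cm.ward_cluster(d)
    with pytest.warns(UserWarning):
        k = cm.kgs_optimal_k(tree, d)
    assert k == 2


# ---------------------------------------------------------------------------
# cluster-level association
# ---------------------------------------------------------------------------

def test_cluster_association_signs(small_microbiome, small_cohort):
    table, _, truth = small_microbiome
    pheno, scores = small_cohort
    idx = scores["total"].to_numpy()
    planted = [t.taxon_id for t in truth.planted_taxa]
    labels = pd.Series(
        [t.cluster for t in truth.planted_taxa], index=planted,
        name="cluster")
    assignment = cm.cluster.ClusterAssignment(labels, k=2)
    res = cm.cluster_association(table, assignment, idx)
    assert res.loc[1, "beta"] < 0 and res.loc[1, "significant"]
    assert res.loc[2, "beta"] > 0 and res.loc[2, "significant"]


def test_singleton_cluster_matches_da_sign(small_microbiome, small_cohort):
    table, _, truth = small_microbiome
    _, scores = small_cohort
    idx = scores["total"].to_numpy()
    taxon = truth.planted_taxa[0].taxon_id
    assignment = cm.cluster.ClusterAssignment(
        pd.Series({taxon: 1}, name="cluster"), k=1)
    res = cm.cluster_association(table, assignment, idx)
    da = cm.da_fit(table, idx)
    assert np.sign(res.loc[1, "beta"]) == np.sign(da.table.loc[taxon, "lfc"])


def test_empty_cluster_rejected(small_microbiome, small_cohort):
    table, _, _ = small_microbiome
    _, scores = small_cohort
    assignment = cm.cluster.ClusterAssignment(
        pd.Series({"not_a_taxon": 1}, name="cluster"), k=1)
    with pytest.raises(ValidationError):
        cm.cluster_association(table, assignment,
                               scores["total"].to_numpy())


def test_dissimilarity_invariant_to_depth_rescaling():
    rng = np.random.default_rng(30)
    counts = rng.integers(100, 1000, size=(50, 8))
    t1 = cm.FeatureTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(50)],
        columns=[f"t{j}" for j in range(8)]))
    scaled = counts.copy()
    scaled[0] *= 13                      # rescale one sample's depth
    t2 = cm.FeatureTable(pd.DataFrame(
        scaled, index=t1.data.index, columns=t1.data.columns))
    d1 = cm.proportionality_dissimilarity(t1)
    d2 = cm.proportionality_dissimilarity(t2)
    # CLR removes per-sample scale (up to pseudo-count distortion)
    assert np.allclose(d1, d2, atol=2e-2)
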