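"""Linear models, BH FDR, PERMANOVA/dispersion/dbRDA/PCoA/factor-fit."""

import itertools

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import pdist, squareform

import crcmicro as cm
from oracles import oneway_permanova_f
from crcmicro.errors import CollinearityError, InsufficientDataError, ValidationError


def _euclidean_dm(points, ids=None):
    d = squareform(pdist(points))
    ids = ids or [f"s{i}" for i in range(points.shape[0])]
    return skbio.DistanceMatrix(d, ids=ids)


# ---------------------------------------------------------------------------
# OLS / BH / interaction
# ---------------------------------------------------------------------------

def test_ols_exact_fit():
    x = np.arange(10.0)
    fit = cm.ols_adjusted(2 * x, x, standardize=False)
    assert fit.beta == pytest.approx(2.0, abs=1e-10)
    assert fit.se == pytest.approx(0.0, abs=1e-8)


def test_ols_standardization_scales_beta():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 4, 300)
    y = 0.5 * x + rng.normal(0, 1, 300)
    per_unit = cm.ols_adjusted(y, x, standardize=False)
    per_sd = cm.ols_adjusted(y, x, standardize=True)
    assert per_sd.beta == pytest.approx(per_unit.beta * x.std(ddof=1),
                                        rel=1e-9)


def test_ols_errors():
    with pytest.raises(InsufficientDataError):
        cm.ols_adjusted([1.0, 2.0], [1.0, 2.0], standardize=False)
    x = np.arange(20.0)
    with pytest.raises(CollinearityError):
        cm.ols_adjusted(x, x, covariates=pd.DataFrame({"dup": x}),
                        standardize=False)


def test_bh_fdr_hand_computation():
    assert cm.bh_fdr([0.02])[0] == pytest.approx(0.02)
    adj = cm.bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])
    assert np.all(cm.bh_fdr([1.0, 1.0, 1.0]) == 1.0)
    p = np.array([0.001, 0.01, 0.1, 0.9])
    assert (cm.bh_fdr(p) >= p).all()
    with pytest.raises(ValidationError):
        cm.bh_fdr([0.5, 1.2])


def test_interaction_detects_sex_specific_slope():
    rng = np.random.default_rng(1)
    n = 2000
    sex = np.where(rng.random(n) < 0.5, "woman", "man")
    x = rng.normal(size=n)
    slope = np.where(sex == "man", 0.2, 0.0)
    y = slope * x + rng.normal(0, 1, n)
    res = cm.interaction_test(y, x, sex, standardize=False)
    assert res.p < 0.05


def test_interaction_constant_sex_errors():
    with pytest.raises(CollinearityError):
        cm.interaction_test(np.zeros(10), np.arange(10.0),
                            np.repeat("woman", 10))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------



def test_permanova_exhaustive_matches_enumeration_oracle():
    """At n=6 with a binary exposure, the exhaustive permutation p equals
    an independently coded enumeration over all 720 orderings."""
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(6, 3))
    pts[:3] += 1.5
    dm = _euclidean_dm(pts)
    labels = np.array([1, 1, 1, 0, 0, 0])

    res = cm.permanova(dm, labels, all_perms=True)

    d2 = dm.data ** 2
    f_obs = oneway_permanova_f(d2, labels)
    count = total = 0
    for perm in itertools.permutations(range(6)):
        f_p = oneway_permanova_f(d2, labels[list(perm)])
        count += f_p >= f_obs - 1e-12
        total += 1
    assert res.pseudo_f == pytest.approx(f_obs, abs=1e-10)
    assert res.p_value == pytest.approx(count / total, abs=1e-12)


def test_permanova_equals_anova_r2_on_euclidean_distances():
    """On Euclidean distances PERMANOVA partitions the same variance as
    direct ANOVA/regression on the coordinates."""
    rng = np.random.default_rng(8)
    n = 40
    x = rng.normal(size=n)
    pts = np.column_stack([1.0 * x + rng.normal(0, 1, n),
                           rng.normal(0, 1, n),
                           rng.normal(0, 1, n)])
    pts -= pts.mean(axis=0)
    dm = _euclidean_dm(pts)
    res = cm.permanova(dm, x, n_perm=99, seed=0)
    # direct multivariate regression R^2 on the coordinates
    X = np.column_stack([np.ones(n), x])
    h = X @ np.linalg.pinv(X)
    ss_model = np.sum((h @ pts) ** 2)
    ss_total = np.sum(pts ** 2)
    assert res.r2 == pytest.approx(ss_model / ss_total, abs=1e-8)


def test_permanova_constant_exposure_degenerate():
    rng = np.random.default_rng(0)
    dm = _euclidean_dm(rng.normal(size=(12, 2)))
    res = cm.permanova(dm, np.ones(12), n_perm=99, seed=0)
    assert res.degenerate
    assert res.r2 == 0.0


def test_permanova_seed_reproducible(small_microbiome, small_cohort):
    table, tree, _ = small_microbiome
    _, scores = small_cohort
    props = cm.relative_abundance(table)
    dm = cm.weighted_unifrac(props, tree)
    idx = scores["total"].to_numpy()
    a = cm.permanova(dm, idx, n_perm=99, seed=42)
    b = cm.permanova(dm, idx, n_perm=99, seed=42)
    assert a.p_value == b.p_value
    assert a.p_value >= 1 / 100


# ---------------------------------------------------------------------------
# PCoA / dbRDA / dispersion / factor fit
# ---------------------------------------------------------------------------

def test_pcoa_reconstructs_euclidean_configuration():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(15, 2))
    dm = _euclidean_dm(pts)
    res = cm.pcoa(dm)
    coords = res.coordinates.to_numpy()
    rebuilt = squareform(pdist(coords))
    assert np.allclose(rebuilt, dm.data, atol=1e-8)


def test_pcoa_two_samples_and_zero_matrix():
    dm = skbio.DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["a", "b"])
    res = cm.pcoa(dm)
    assert np.allclose(np.abs(res.coordinates.to_numpy()[:, 0]), 0.5)
    zero = skbio.DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
    res0 = cm.pcoa(zero)
    assert np.allclose(res0.coordinates.to_numpy(), 0.0)


def test_pcoa_matches_skbio_eigenvalues(small_microbiome):
    table, tree, _ = small_microbiome
    props = cm.relative_abundance(table)
    dm = cm.weighted_unifrac(props, tree)
    ours = cm.pcoa(dm)
    ref = skbio.stats.ordination.pcoa(dm, method="eigh")
    k = 5
    assert np.allclose(ours.eigenvalues[:k], ref.eigvals.to_numpy()[:k],
                       atol=1e-8)


def test_pcoa_positive_eigenvalues_sum_to_trace(small_microbiome):
    table, tree, _ = small_microbiome
    props = cm.relative_abundance(table)
    dm = cm.weighted_unifrac(props, tree)
    res = cm.pcoa(dm)
    from crcmicro.assoc import _gower_center
    trace = np.trace(_gower_center(dm.data))
    assert (res.eigenvalues[res.eigenvalues > 0].sum()
            - res.negative_eigenvalue_mass) == pytest.approx(trace, rel=1e-8)


def test_dbrda_design_equal_to_first_axis_loads_one_axis():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(30, 3)) * np.array([3.0, 1.0, 0.5])
    dm = _euclidean_dm(pts)
    axis1 = cm.pcoa(dm).coordinates.iloc[:, 0]
    res = cm.dbrda(dm, pd.DataFrame({"x": axis1}), n_perm=99, seed=0)
    assert res.axis_proportions[0] == pytest.approx(1.0, abs=1e-10)


def test_dbrda_planted_gradient_concentrates_on_axis_one():
    rng = np.random.default_rng(11)
    n = 80
    grad = rng.normal(size=n)
    pts = np.column_stack([2.0 * grad, rng.normal(0, 1, n),
                           rng.normal(0, 1, n)])
    dm = _euclidean_dm(pts)
    res = cm.dbrda(dm, pd.DataFrame({"g": grad}), n_perm=99, seed=0)
    assert res.axis_proportions[0] > 0.75
    assert res.p_value <= 0.05


def test_dispersion_detects_variance_ratio():
    rng = np.random.default_rng(6)
    a = rng.normal(0, 1, size=(30, 2))
    b = rng.normal(0, 2, size=(30, 2))
    dm = _euclidean_dm(np.vstack([a, b]))
    groups = np.repeat(["a", "b"], 30)
    res = cm.beta_dispersion(dm, groups, n_perm=199, seed=0)
    assert res.p_value < 0.05


def test_dispersion_duplicated_group_has_zero_spread():
    pts = np.vstack([np.tile([0.0, 0.0], (5, 1)),
                     np.random.default_rng(0).normal(0, 1, size=(5, 2))])
    dm = _euclidean_dm(pts)
    res = cm.beta_dispersion(dm, np.repeat(["dup", "spread"], 5),
                             n_perm=199, seed=0)
    assert res.f_statistic > 5
    assert res.p_value < 0.05


def test_dispersion_matches_skbio_f(small_microbiome, small_cohort):
    """F statistic agrees with skbio's PERMDISP (spatial median test)."""
    table, tree, _ = small_microbiome
    _, scores = small_cohort
    props = cm.relative_abundance(table)
    dm = cm.weighted_unifrac(props, tree)
    groups = (scores["quintile"] >= 4).map({True: "hi", False: "lo"})
    ours = cm.beta_dispersion(dm, groups.to_numpy(), n_perm=99, seed=0)
    ref = skbio.stats.distance.permdisp(
        dm, groups.to_numpy(), test="median", permutations=0,
        dimensions=dm.shape[0] - 1)
    assert ours.f_statistic == pytest.approx(float(ref["test statistic"]),
                                             rel=1e-3)


def test_dispersion_singleton_group_rejected():
    dm = _euclidean_dm(np.random.default_rng(0).normal(size=(5, 2)))
    with pytest.raises(ValidationError):
        cm.beta_dispersion(dm, ["a", "a", "a", "a", "b"], n_perm=99)


def test_factor_fit_perfect_split():
    coords = np.vstack([np.tile([5.0, 0.0], (6, 1)),
                        np.tile([-5.0, 0.0], (6, 1))])
    coords += np.random.default_rng(0).normal(0, 0.01, coords.shape)
    res = cm.factor_fit(coords, np.repeat(["a", "b"], 6), n_perm=199, seed=0)
    assert res.r2 > 0.99
    assert res.p_value == pytest.approx(1 / 200)


def test_factor_fit_requires_two_groups_and_two_axes():
    coords = np.random.default_rng(0).normal(size=(8, 2))
    with pytest.raises(ValidationError):
        cm.factor_fit(coords, np.repeat("a", 8), n_perm=99)
    with pytest.raises(ValidationError):
        cm.factor_fit(coords[:, :1], np.repeat(["a", "b"], 4), n_perm=99)
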