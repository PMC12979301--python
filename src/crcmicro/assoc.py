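"""Covariate-adjusted association statistics.

Alpha-diversity associations are ordinary least squares with the study's
adjustment set (sex, age, energy intake, smoking, microbiome-altering
medication, and BMI for non-anthropometric exposures), with
Benjamini-Hochberg FDR across exposures.  Beta-diversity associations
operate on a distance matrix: PERMANOVA (marginal pseudo-F and R^2 for
the exposure with covariates retained), a permutation dispersion test
(distance to the group spatial median in principal-coordinate space),
distance-based redundancy analysis (constrained variance of the full
design), principal coordinates analysis, and a centroid-r^2 "factor fit"
of group labels onto ordination axes.

Permutation p-values use the add-one convention
``p = (1 + #{permuted statistic >= observed}) / (1 + n_perm)`` and are
reproducible under a fixed seed; permutations shuffle raw sample rows.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import (
    AlignmentError,
    CollinearityError,
    InsufficientDataError,
    ValidationError,
)

DEFAULT_N_PERM = 999


# ---------------------------------------------------------------------------
# Linear models
# ---------------------------------------------------------------------------

@dataclass
class LinearModelResult:
    """OLS fit summary focused on one exposure term.

    ``summary`` has one row per model term with columns
    ``beta, se, t, p`` (and ``fdr_p`` when adjusted across a family).
    """

    summary: pd.DataFrame
    exposure: str
    nobs: int

    @property
    def beta(self) -> float:
        return float(self.summary.loc[self.exposure, "beta"])

    @property
    def se(self) -> float:
        return float(self.summary.loc[self.exposure, "se"])

    @property
    def p(self) -> float:
        return float(self.summary.loc[self.exposure, "p"])


def _as_design(covariates) -> pd.DataFrame | None:
    if covariates is None:
        return None
    cov = pd.DataFrame(covariates).copy()
    # dummy-code any non-numeric columns, dropping the first level
    out = {}
    for name, col in cov.items():
        if np.issubdtype(np.asarray(col).dtype, np.number):
            out[name] = np.asarray(col, dtype=float)
        else:
            values = pd.Series(col).astype("category")
            for level in values.cat.categories[1:]:
                out[f"{name}[{level}]"] = (values == level).to_numpy(float)
    return pd.DataFrame(out, index=cov.index)


def _check_design(X: np.ndarray):
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(f"n={n} observations for p={p} terms")
    if np.linalg.matrix_rank(X) < p:
        raise CollinearityError("design matrix is rank deficient")


def ols_adjusted(
    y,
    exposure,
    covariates=None,
    standardize: bool = True,
    exposure_name: str = "exposure",
) -> LinearModelResult:
    """OLS of ``y`` on the exposure plus covariates (with intercept).

    Continuous exposures are standardized to unit variance by default so
    coefficients are per SD of the exposure; pass ``standardize=False``
    for indicator or point-scaled exposures.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if standardize:
        sd = x.std(ddof=1)
        if sd == 0:
            raise CollinearityError("exposure is constant")
        x = (x - x.mean()) / sd
    cov = _as_design(covariates)
    pieces = [pd.Series(x, name=exposure_name)]
    if cov is not None:
        pieces.append(cov.reset_index(drop=True))
    X = pd.concat(pieces, axis=1)
    X.insert(0, "intercept", 1.0)
    _check_design(X.to_numpy())
    fit = sm.OLS(y, X).fit()
    summary = pd.DataFrame({
        "beta": fit.params, "se": fit.bse, "t": fit.tvalues,
        "p": fit.pvalues,
    })
    return LinearModelResult(summary, exposure_name, int(fit.nobs))


def interaction_test(
    y,
    exposure,
    sex,
    covariates=None,
    standardize: bool = True,
) -> LinearModelResult:
    """Wald test of an exposure x sex product term.

    The model contains the exposure, a sex indicator, their product and
    the covariates; the focus term is the product.
    """
    x = np.asarray(exposure, dtype=float)
    if standardize:
        sd = x.std(ddof=1)
        if sd == 0:
            raise CollinearityError("exposure is constant")
        x = (x - x.mean()) / sd
    sex = np.asarray(sex)
    levels = np.unique(sex)
    if len(levels) < 2:
        raise CollinearityError("sex is constant; no interaction is testable")
    ind = (sex == levels[1]).astype(float)
    design = pd.DataFrame({
        "exposure": x,
        f"sex[{levels[1]}]": ind,
        "exposure:sex": x * ind,
    })
    cov = _as_design(covariates)
    if cov is not None:
        design = pd.concat([design, cov.reset_index(drop=True)], axis=1)
    design.insert(0, "intercept", 1.0)
    _check_design(design.to_numpy())
    fit = sm.OLS(np.asarray(y, dtype=float), design).fit()
    summary = pd.DataFrame({
        "beta": fit.params, "se": fit.bse, "t": fit.tvalues,
        "p": fit.pvalues,
    })
    return LinearModelResult(summary, "exposure:sex", int(fit.nobs))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Distance-matrix machinery
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()

def _hat(X: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def _align_distance(dm: skbio.DistanceMatrix, index) -> np.ndarray:
    if index is None:
        return dm.data
    ids = [str(i) for i in index]
    if set(ids) != set(dm.ids):
        raise AlignmentError("distance matrix and design ids differ")
    return dm.filter(ids).data


@dataclass
class PermanovaResult:
    term: str
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    degenerate: bool = False


def permanova(
    dm: skbio.DistanceMatrix,
    exposure,
    covariates=None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    all_perms: bool = False,
    term: str = "exposure",
    ids=None,
) -> PermanovaResult:
    """Marginal PERMANOVA of one exposure with covariates retained.

    Sums of squares are partitioned on the Gower-centered inner-product
    matrix; the exposure's marginal sum of squares is the gain in
    explained trace of the full design over the covariate-only design.
    The permutation null shuffles raw sample rows.  With
    ``all_perms=True`` every ordering is enumerated (exact p; only
    sensible for tiny n).
    """
    d = _align_distance(dm, ids)
    n = d.shape[0]
    g = _gower_center(d)

    exp_design = _as_design(pd.DataFrame({term: np.asarray(exposure)}))
    cov = _as_design(covariates)
    ones = np.ones((n, 1))
    X_red = (np.hstack([ones, cov.to_numpy()]) if cov is not None else ones)
    X_full = np.hstack([X_red, exp_design.to_numpy()])

    h_red = _hat(X_red)
    h_full = _hat(X_full)
    rank_full = int(round(np.trace(h_full)))
    rank_red = int(round(np.trace(h_red)))
    df_exp = rank_full - rank_red
    if df_exp == 0:
        return PermanovaResult(term, 0.0, 0.0, 1.0, 0, degenerate=True)
    df_res = n - rank_full
    if df_res <= 0:
        raise InsufficientDataError("no residual degrees of freedom")

    ss_total = np.trace(g)

    def f_stat(gp):
        ss_exp = np.sum(h_full * gp) - np.sum(h_red * gp)
        ss_res = np.trace(gp) - np.sum(h_full * gp)
        return (ss_exp / df_exp) / (ss_res / df_res), ss_exp

    f_obs, ss_exp = f_stat(g)
    r2 = ss_exp / ss_total if ss_total > 0 else 0.0

    if all_perms:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.asarray(perm)
            f_p, _ = f_stat(g[np.ix_(idx, idx)])
            count += f_p >= f_obs - 1e-12
            total += 1
        return PermanovaResult(term, f_obs, r2, count / total, total)

    if n_perm < 99:
        raise ValidationError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        f_p, _ = f_stat(g[np.ix_(idx, idx)])
        count += f_p >= f_obs - 1e-12
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(term, f_obs, r2, p, n_perm)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame          # samples x axes
    eigenvalues: np.ndarray            # all eigenvalues, descending
    constrained_proportion: float | None = None
    axis_proportions: np.ndarray | None = None
    p_value: float | None = None
    negative_eigenvalue_mass: float = 0.0
    warnings: list[str] = field(default_factory=list)


def pcoa(dm: skbio.DistanceMatrix) -> OrdinationResult:
    """Classical principal coordinates analysis of a distance matrix.

    Coordinates are eigenvectors scaled by the square root of positive
    eigenvalues; negative eigenvalues are reported, not embedded.
    """
    d = dm.data
    g = _gower_center(d)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-10 * max(1.0, np.abs(eigval).max())
    pos = eigval > tol
    if pos.any():
        coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    else:
        coords = np.zeros((d.shape[0], 1))
    neg_mass = float(-eigval[eigval < -tol].sum())
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=eigval,
        negative_eigenvalue_mass=neg_mass,
    )


def dbrda(
    dm: skbio.DistanceMatrix,
    design,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    ids=None,
) -> OrdinationResult:
    """Distance-based redundancy analysis of the full design.

    The principal-coordinate embedding is regressed on the design
    (exposure plus confounders); the constrained proportion is the share
    of total (positive-eigenvalue) variance explained, with a
    permutation test of the overall pseudo-F.  Axis proportions are the
    shares of the constrained variance carried by each constrained axis.
    """
    d = _align_distance(dm, ids)
    ord_res = pcoa(skbio.DistanceMatrix(d, ids=[str(i) for i in (
        ids if ids is not None else dm.ids)]))
    y = ord_res.coordinates.to_numpy()
    n = y.shape[0]

    X = _as_design(pd.DataFrame(design)).to_numpy()
    X = np.hstack([np.ones((n, 1)), X])
    _check_design(X)
    # thin orthonormal basis of the design column space: projections cost
    # O(n p k) instead of the O(n^2 k) full hat matrix
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    rank = q.shape[1]
    df_model, df_res = rank - 1, n - rank

    yc = y - y.mean(axis=0)
    fitted = q @ (q.T @ yc)
    ss_con = float(np.sum(fitted ** 2))
    ss_tot = float(np.sum(yc ** 2))
    proportion = ss_con / ss_tot if ss_tot > 0 else 0.0

    # constrained axes: singular structure of the fitted values
    _, svals, _ = np.linalg.svd(fitted, full_matrices=False)
    axis_eig = svals ** 2
    axis_eig = axis_eig[axis_eig > 1e-12 * max(1.0, axis_eig.max())]
    axis_props = (axis_eig / axis_eig.sum() if axis_eig.size else
                  np.array([]))

    def f_stat(yp):
        ssc = np.sum((q.T @ yp) ** 2)
        return (ssc / df_model) / ((np.sum(yp ** 2) - ssc) / df_res)

    f_obs = f_stat(yc)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += f_stat(yc[rng.permutation(n)]) >= f_obs - 1e-12
    p = (1 + count) / (1 + n_perm)

    warnings_list = []
    total_mass = float(np.abs(ord_res.eigenvalues).sum())
    if total_mass > 0 and ord_res.negative_eigenvalue_mass > 0.05 * total_mass:
        warnings_list.append(
            "negative-eigenvalue mass exceeds 5% of the total")
    return OrdinationResult(
        coordinates=ord_res.coordinates,
        eigenvalues=ord_res.eigenvalues,
        constrained_proportion=proportion,
        axis_proportions=axis_props,
        p_value=p,
        negative_eigenvalue_mass=ord_res.negative_eigenvalue_mass,
        warnings=warnings_list,
    )


# ---------------------------------------------------------------------------
# Dispersion and factor fit
# ---------------------------------------------------------------------------

def _spatial_median(points: np.ndarray, n_iter: int = 200,
                    tol: float = 1e-10) -> np.ndarray:
    """Geometric median by Weiszfeld iteration."""
    med = points.mean(axis=0)
    for _ in range(n_iter):
        diff = points - med
        dist = np.sqrt((diff ** 2).sum(axis=1))
        if np.any(dist < 1e-12):
            return med
        w = 1.0 / dist
        new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.max(np.abs(new - med)) < tol:
            return new
        med = new
    return med


def _dispersion_f(coords: np.ndarray, codes: np.ndarray,
                  n_groups: int) -> float:
    dists = np.empty(coords.shape[0])
    for gidx in range(n_groups):
        mask = codes == gidx
        med = _spatial_median(coords[mask])
        dists[mask] = np.sqrt(((coords[mask] - med) ** 2).sum(axis=1))
    grand = dists.mean()
    ss_between = ss_within = 0.0
    for gidx in range(n_groups):
        d = dists[codes == gidx]
        ss_between += d.size * (d.mean() - grand) ** 2
        ss_within += ((d - d.mean()) ** 2).sum()
    df_b = n_groups - 1
    df_w = dists.size - n_groups
    if ss_within == 0:
        return math.inf
    return (ss_between / df_b) / (ss_within / df_w)


@dataclass
class DispersionResult:
    f_statistic: float
    p_value: float
    n_permutations: int


def beta_dispersion(
    dm: skbio.DistanceMatrix,
    groups,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    ids=None,
    dimensions: int | None = None,
) -> DispersionResult:
    """Permutation test of multivariate dispersion (PERMDISP).

    Each sample's distance to its group's spatial median in
    principal-coordinate space feeds a one-way F statistic whose null
    distribution comes from permuting group labels.  ``dimensions``
    truncates the embedding to the leading axes (all by default; large
    cohorts commonly use ~10, as reference implementations do).
    """
    d = _align_distance(dm, ids)
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_counts=False), None
    codes = np.searchsorted(labels, groups)
    if len(labels) < 2:
        raise ValidationError("dispersion test needs at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValidationError("each group needs at least 2 members")

    ord_res = pcoa(skbio.DistanceMatrix(d))
    coords = ord_res.coordinates.to_numpy()
    if dimensions is not None:
        coords = coords[:, :dimensions]

    f_obs = _dispersion_f(coords, codes, len(labels))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_p = _dispersion_f(coords, codes[rng.permutation(codes.size)],
                            len(labels))
        count += f_p >= f_obs - 1e-12
    return DispersionResult(f_obs, (1 + count) / (1 + n_perm), n_perm)


@dataclass
class FactorFitResult:
    r2: float
    p_value: float
    n_permutations: int


def factor_fit(
    coords,
    factor,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> FactorFitResult:
    """Centroid-r^2 fit of group labels onto ordination coordinates.

    ``r^2 = 1 - SS_within_group_centroids / SS_total`` on the supplied
    axes (typically the first two principal coordinates), with a
    label-permutation p-value.
    """
    coords = np.asarray(pd.DataFrame(coords), dtype=float)
    if coords.ndim != 2 or coords.shape[1] < 2:
        raise ValidationError("factor_fit needs at least 2 ordination axes")
    factor = np.asarray(factor)
    labels = np.unique(factor)
    if len(labels) < 2:
        raise ValidationError("factor_fit needs at least 2 groups")
    codes = np.searchsorted(labels, factor)

    centered = coords - coords.mean(axis=0)
    ss_total = float(np.sum(centered ** 2))

    def r2_stat(c):
        ss_within = 0.0
        for gidx in range(len(labels)):
            pts = coords[c == gidx]
            ss_within += float(np.sum((pts - pts.mean(axis=0)) ** 2))
        return 1.0 - ss_within / ss_total if ss_total > 0 else 0.0

    r2_obs = r2_stat(codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += r2_stat(codes[rng.permutation(codes.size)]) >= r2_obs - 1e-12
    return FactorFitResult(r2_obs, (1 + count) / (1 + n_perm), n_perm)
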