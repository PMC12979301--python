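"""Species co-occurrence clustering by proportionality.

Index-associated species (FDR-significant and robust to the
pseudo-count screen) are clustered by how proportionally they co-vary
across samples: on centered log-ratio (CLR) transformed counts, the
proportionality of two taxa x, y is

    rho(x, y) = 2 cov(x, y) / (var x + var y)

(1 for perfectly proportional pairs, 0 for unrelated ones), and
``1 - rho`` in [0, 2] is the dissimilarity fed to Ward's minimum
variance linkage.  The number of clusters is chosen by the
Kelley-Gardner-Sutcliffe penalty: for each cut k, the mean within-
cluster spread is linearly rescaled across k onto [1, n-1] and k is
added; the argmin (smaller k on ties) wins.  Each cluster's per-sample
abundance, summarized as the CLR mean over member taxa, is then
regressed on the index with the study covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .assoc import LinearModelResult, ols_adjusted
from .errors import DegenerateTaxonError, ValidationError
from .prep import FeatureTable


def clr_transform(counts: FeatureTable, pseudo_count: float = 1.0) -> pd.DataFrame:
    """Per-sample centered log-ratio of ``count + pseudo_count``."""
    logc = np.log(counts.data.to_numpy(dtype=float) + pseudo_count)
    clr = logc - logc.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.data.index,
                        columns=counts.data.columns)


def proportionality_dissimilarity(
    counts: FeatureTable,
    pseudo_count: float = 1.0,
) -> pd.DataFrame:
    """Taxon x taxon dissimilarity ``1 - rho`` on CLR values."""
    if counts.n_taxa < 2:
        raise ValidationError("need at least 2 taxa to cluster")
    clr = clr_transform(counts, pseudo_count).to_numpy()
    var = clr.var(axis=0, ddof=1)
    if np.any(var <= 0):
        bad = [t for t, v in zip(counts.taxon_ids, var) if v <= 0]
        raise DegenerateTaxonError(f"zero-variance taxa: {bad}")
    cov = np.cov(clr, rowvar=False)
    rho = 2 * cov / (var[:, None] + var[None, :])
    diss = 1.0 - rho
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2, 0.0, 2.0)
    return pd.DataFrame(diss, index=counts.taxon_ids,
                        columns=counts.taxon_ids)


def ward_cluster(dissimilarity: pd.DataFrame) -> "LinkageResult":
    """Ward's minimum-variance agglomeration of a dissimilarity matrix.

    Taxa are sorted by id first so the merge order is invariant to the
    input column order.  Returns the linkage with its leaf labels.
    """
    diss = pd.DataFrame(dissimilarity)
    if diss.isna().to_numpy().any():
        raise ValidationError("dissimilarity contains NaN")
    order = np.argsort(diss.index.to_numpy())
    diss = diss.iloc[order, order]
    condensed = squareform(diss.to_numpy(), checks=False)
    z = linkage(condensed, method="ward")
    return LinkageResult(z, list(diss.index))


@dataclass
class LinkageResult:
    """A linkage matrix together with the leaf labels it refers to."""

    linkage: np.ndarray
    labels: list

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, k: int) -> pd.Series:
        flat = fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")


def _mean_within_spread(diss: np.ndarray, labels: np.ndarray) -> float:
    """Mean over multi-member clusters of the average within-cluster
    dissimilarity (singletons carry no spread information and are
    excluded, following the common KGS implementations)."""
    spreads = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            continue
        sub = diss[np.ix_(idx, idx)]
        spreads.append(sub[np.triu_indices(idx.size, k=1)].mean())
    return float(np.mean(spreads)) if spreads else 0.0


def kgs_optimal_k(
    tree: LinkageResult,
    dissimilarity: pd.DataFrame,
) -> int:
    """Kelley-Gardner-Sutcliffe choice of the number of clusters.

    For every cut k in 2..n-1 the mean within-cluster spread is computed,
    the spreads are linearly rescaled onto [1, n-1], and the penalty
    ``rescaled spread + k`` is minimized (ties to the smaller k).
    """
    n = tree.n_leaves
    if n < 3:
        raise ValidationError("KGS selection needs at least 3 leaves")
    diss = pd.DataFrame(dissimilarity).loc[tree.labels, tree.labels].to_numpy()
    ks = np.arange(2, n)
    spreads = np.array([
        _mean_within_spread(diss, tree.cut(int(k)).to_numpy()) for k in ks])
    lo, hi = spreads.min(), spreads.max()
    if hi - lo < 1e-12:
        warnings.warn("KGS: all within-cluster spreads equal; returning k=2",
                      stacklevel=2)
        return 2
    rescaled = (n - 2) * (spreads - lo) / (hi - lo) + 1
    penalty = rescaled + ks
    return int(ks[int(np.argmin(penalty))])


@dataclass
class ClusterAssignment:
    """Taxon -> cluster labels plus per-cluster association results."""

    labels: pd.Series
    k: int
    associations: pd.DataFrame | None = None


def assign_clusters(
    counts: FeatureTable,
    taxa: list[str] | None = None,
    pseudo_count: float = 1.0,
    k: int | None = None,
) -> tuple[ClusterAssignment, LinkageResult, pd.DataFrame]:
    """Cluster (a subset of) taxa by proportionality with Ward linkage.

    ``taxa`` restricts the input, typically to the index-associated
    species that passed the robustness screen.  ``k`` overrides the KGS
    choice.
    """
    sub = counts
    if taxa is not None:
        if len(taxa) < 2:
            raise ValidationError("need at least 2 selected taxa")
        sub = FeatureTable(counts.data[list(taxa)],
                           counts.taxonomy, counts.mode)
    diss = proportionality_dissimilarity(sub, pseudo_count)
    tree = ward_cluster(diss)
    if k is None:
        k = kgs_optimal_k(tree, diss) if tree.n_leaves >= 3 else 1
    labels = tree.cut(k) if k > 1 else pd.Series(
        1, index=tree.labels, name="cluster")
    return ClusterAssignment(labels, int(k)), tree, diss


def cluster_association(
    counts: FeatureTable,
    assignment: ClusterAssignment,
    index_scores,
    covariates=None,
    pseudo_count: float = 1.0,
    aggregation: str = "clr_mean",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cluster regression of abundance on the lifestyle index.

    The per-sample cluster abundance is the CLR mean over member taxa
    (``aggregation="clr_mean"``) or the log of the summed relative
    abundance (``aggregation="log_relabund"``).  Returns one row per
    cluster with ``beta, se, p, significant``.
    """
    clr = clr_transform(counts, pseudo_count)
    if aggregation not in ("clr_mean", "log_relabund"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    rows = []
    for c in sorted(assignment.labels.unique()):
        members = assignment.labels.index[assignment.labels == c]
        if len(members) == 0:
            raise ValidationError(f"cluster {c} is empty")
        missing = [m for m in members if m not in clr.columns]
        if missing:
            raise ValidationError(f"cluster {c} taxa absent from the table: "
                                  f"{missing}")
        if aggregation == "clr_mean":
            abundance = clr[list(members)].mean(axis=1).to_numpy()
        else:
            totals = counts.data.sum(axis=1).to_numpy(dtype=float)
            mass = counts.data[list(members)].sum(axis=1).to_numpy(float)
            abundance = np.log((mass + pseudo_count) / totals)
        fit = ols_adjusted(abundance, index_scores, covariates,
                           standardize=False, exposure_name="index")
        rows.append({"cluster": c, "n_taxa": len(members),
                     "beta": fit.beta, "se": fit.se, "p": fit.p,
                     "significant": fit.p < alpha})
    return pd.DataFrame(rows).set_index("cluster")
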