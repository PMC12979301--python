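"""Alpha diversity (Shannon) and beta diversity (weighted UniFrac).

Shannon entropy is computed on species-level raw counts with the natural
logarithm; ``0 * ln 0`` is taken as 0.  Weighted UniFrac follows the
branch-sum definition: for samples A and B,

    d(A, B) = sum over branches  b_len * | P_A(subtree) - P_B(subtree) |

where ``P(subtree)`` is the total relative abundance of the taxa below
the branch.  The unnormalized ("raw") variant is the default; the
normalized variant divides by ``sum b_len * (P_A + P_B)``.  The whole
distance matrix is computed from a single postorder traversal that
accumulates per-branch sample mass, then a weighted Manhattan distance
over branches.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
import skbio
from scipy.spatial.distance import pdist, squareform

from .errors import AlignmentError, DegenerateSampleError, FormatError, ValidationError
from .prep import FeatureTable


def shannon(table: FeatureTable) -> pd.Series:
    """Per-sample Shannon index H = -sum p_i ln p_i (natural log)."""
    if table.mode != "counts":
        raise ValidationError("shannon expects species-level raw counts")
    counts = table.data.to_numpy(dtype=float)
    sums = counts.sum(axis=1)
    if np.any(sums <= 0):
        bad = [s for s, t in zip(table.sample_ids, sums) if t <= 0]
        raise DegenerateSampleError(f"zero-sum samples: {bad}")
    # scipy's entropy normalizes rows and treats 0 log 0 as 0
    h = scipy.stats.entropy(counts, axis=1)
    return pd.Series(h, index=table.data.index, name="shannon")


def _branch_mass_matrix(table: FeatureTable, tree: skbio.TreeNode):
    """Per-branch cumulative sample mass and branch lengths.

    Returns ``(masses, lengths)`` where ``masses[i, b]`` is the total
    proportion in sample i of the taxa descending through branch b.
    """
    props = table.data
    leaf_names = {leaf.name for leaf in tree.tips()}
    missing = [t for t in props.columns if t not in leaf_names]
    if missing:
        raise AlignmentError(
            f"taxa absent from the tree: {missing[:5]}"
            + ("..." if len(missing) > 5 else ""))

    x = props.to_numpy(dtype=float)
    col = {t: j for j, t in enumerate(props.columns)}
    n = x.shape[0]
    masses, lengths = [], []
    # postorder accumulation: each node's mass is the sum of its children's
    node_mass: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            m = (x[:, col[node.name]] if node.name in col
                 else np.zeros(n))
        else:
            m = np.zeros(n)
            for child in node.children:
                m = m + node_mass.pop(id(child))
        node_mass[id(node)] = m
        if node.parent is not None:          # the root bears no branch
            if node.length is None or node.length < 0:
                raise FormatError(
                    f"branch above {node.name!r} lacks a valid length")
            masses.append(m)
            lengths.append(node.length)
    return np.column_stack(masses), np.asarray(lengths)


def weighted_unifrac(
    table: FeatureTable,
    tree: skbio.TreeNode,
    normalized: bool = False,
) -> skbio.DistanceMatrix:
    """Pairwise weighted UniFrac distances between all samples.

    ``table`` must be in proportions mode and every taxon must be a leaf
    of ``tree``.  With ``normalized=True`` each pair's branch sum is
    divided by the branch-length-weighted total mass of the two samples.
    """
    if table.mode != "proportions":
        raise ValidationError(
            "weighted UniFrac expects relative abundances; "
            "call relative_abundance() first")
    masses, lengths = _branch_mass_matrix(table, tree)
    d = pdist(masses, metric="cityblock", w=lengths)
    if normalized:
        s = masses @ lengths                 # per-sample weighted mass
        denom = s[:, None] + s[None, :]
        denom_condensed = squareform(denom, checks=False)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom_condensed > 0, d / denom_condensed, 0.0)
    dm = skbio.DistanceMatrix(squareform(d), ids=table.sample_ids)
    dm.method = "weighted_unifrac"
    return dm
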