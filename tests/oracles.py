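"""Independent brute-force oracles used by the test suite.

Each function here re-derives a quantity from first principles with the
slowest, most transparent algorithm available, deliberately sharing no
code with the package implementation it checks.
"""

import numpy as np


def naive_weighted_unifrac(props, tree, taxa, normalized=False):
    """Per-pair branch-sum weighted UniFrac by explicit tree recursion."""

    def subtree_mass(node, sample):
        if node.is_tip():
            return sample.get(node.name, 0.0)
        return sum(subtree_mass(c, sample) for c in node.children)

    def pair(a, b):
        num = den = 0.0
        for node in tree.traverse(include_self=False):
            ma, mb = subtree_mass(node, a), subtree_mass(node, b)
            num += node.length * abs(ma - mb)
            den += node.length * (ma + mb)
        return num / den if normalized else num

    n = props.shape[0]
    out = np.zeros((n, n))
    rows = [dict(zip(taxa, props[i])) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pair(rows[i], rows[j])
    return out


def oneway_permanova_f(d2, labels):
    """Classical one-way pseudo-F from squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(np.unique(labels))
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def naive_ward(d):
    """O(n^3) Lance-Williams Ward agglomeration.

    Returns a list of (sorted leaf ids of the newly merged cluster,
    merge height) in merge order.
    """
    n = d.shape[0]
    active = {i: [i] for i in range(n)}
    dist = {(i, j): float(d[i, j])
            for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        (ci, cj), h = min(dist.items(), key=lambda kv: kv[1])
        leaves_i, leaves_j = active.pop(ci), active.pop(cj)
        new = leaves_i + leaves_j
        merges.append((sorted(new), h))
        ni, nj = len(leaves_i), len(leaves_j)
        new_dist = {}
        for ck, leaves_k in active.items():
            nk = len(leaves_k)
            dik = dist[tuple(sorted((ci, ck)))]
            djk = dist[tuple(sorted((cj, ck)))]
            val = np.sqrt(((ni + nk) * dik ** 2 + (nj + nk) * djk ** 2
                           - nk * h ** 2) / (ni + nj + nk))
            new_dist[tuple(sorted((ck, next_id)))] = val
        dist = {k: v for k, v in dist.items()
                if ci not in k and cj not in k}
        dist.update(new_dist)
        active[next_id] = new
        next_id += 1
    return merges


def scipy_linkage_merges(linkage_result):
    """Convert a LinkageResult into the same merge-list form."""
    z = linkage_result.linkage
    n = z.shape[0] + 1
    clusters = {i: [i] for i in range(n)}
    merges = []
    for row_idx, (a, b, h, _) in enumerate(z):
        new = clusters[int(a)] + clusters[int(b)]
        merges.append((sorted(new), h))
        clusters[n + row_idx] = new
    return merges
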