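"""Alpha- and beta-diversity measures.

Alpha: bias-corrected Chao1 richness, Shannon entropy (nats) and inverse
Simpson.  Beta: Bray-Curtis, Jaccard (quantitative ``2B/(1+B)`` by
default, binary on request) and unweighted UniFrac over a rooted
phylogeny.  Implementations follow the standard definitions; tests hold
them to brute-force oracles and to scikit-bio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .io import CommunityTable

ALPHA_METRICS = ("chao1", "shannon", "inv_simpson")


def chao1(counts) -> float:
    """Bias-corrected Chao1: ``S_obs + F1(F1-1) / (2(F2+1))``."""
    x = np.asarray(counts, dtype=float)
    _check_counts(x)
    if not np.allclose(x % 1, 0):
        raise ValueError("chao1 requires integer counts")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts) -> float:
    """Shannon entropy in nats: ``-sum p_i ln p_i``."""
    x = np.asarray(counts, dtype=float)
    _check_counts(x)
    p = x[x > 0] / x.sum()
    return float(-(p * np.log(p)).sum())


def inv_simpson(counts) -> float:
    """Inverse Simpson index: ``1 / sum p_i^2``."""
    x = np.asarray(counts, dtype=float)
    _check_counts(x)
    p = x / x.sum()
    return float(1.0 / (p**2).sum())


def _check_counts(x: np.ndarray) -> None:
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if x.sum() <= 0:
        raise ValueError("counts sum to zero")


def alpha_diversity(counts, metric: str) -> float:
    """Dispatch one alpha metric (``chao1`` | ``shannon`` | ``inv_simpson``)."""
    try:
        fn = {"chao1": chao1, "shannon": shannon, "inv_simpson": inv_simpson}[metric]
    except KeyError:
        raise ValueError(f"unknown alpha metric {metric!r}") from None
    return fn(counts)


def alpha_table(table: CommunityTable) -> pd.DataFrame:
    """Per-sample alpha diversity frame with one column per metric."""
    rows = {
        m: [alpha_diversity(row, m) for row in table.df.to_numpy()]
        for m in ALPHA_METRICS
    }
    return pd.DataFrame(rows, index=table.df.index)


# ---------------------------------------------------------------------------
# pairwise dissimilarities


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined: both vectors all-zero")
    return float(np.abs(x - y).sum() / denom)


def jaccard(x, y, binary: bool = False) -> float:
    """Jaccard dissimilarity.

    Quantitative dialect (default): ``2B / (1 + B)`` with B = Bray-Curtis.
    Binary dialect: ``1 - |A ∩ B| / |A ∪ B|`` on the nonzero supports.
    """
    if binary:
        a = np.asarray(x) > 0
        b = np.asarray(y) > 0
        union = (a | b).sum()
        if union == 0:
            raise ValueError("Jaccard undefined: both vectors all-zero")
        return float(1.0 - (a & b).sum() / union)
    bc = bray_curtis(x, y)
    return float(2.0 * bc / (1.0 + bc))


def _branch_incidence(tree: TreeNode, asv_ids: list[str]):
    """(lengths, incidence) over non-root branches.

    ``incidence[b, j]`` is True when leaf ``asv_ids[j]`` descends through
    branch ``b``; lengths are the branch lengths.  Missing-from-tree ASVs
    raise; branches with no table leaves below them are kept (they simply
    never contribute).
    """
    pos = {a: j for j, a in enumerate(asv_ids)}
    tips = {t.name for t in tree.tips()}
    missing = [a for a in asv_ids if a not in tips]
    if missing:
        raise ValueError(f"ASV {missing[0]!r} is not a leaf of the tree")
    lengths, rows = [], []
    for node in tree.postorder(include_self=False):
        mask = np.zeros(len(asv_ids), dtype=bool)
        for tip in node.tips(include_self=True):
            j = pos.get(tip.name)
            if j is not None:
                mask[j] = True
        lengths.append(float(node.length or 0.0))
        rows.append(mask)
    return np.asarray(lengths), np.asarray(rows)


def unweighted_unifrac(table: CommunityTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac distances between all sample pairs.

    For each pair, the summed length of branches leading only to leaves
    present in exactly one of the samples, divided by the summed length of
    branches leading to leaves present in either.  Presence is any nonzero
    abundance.  Computed via a per-branch incidence matrix.
    """
    lengths, incidence = _branch_incidence(tree, table.asv_ids)
    presence = table.df.to_numpy() > 0
    # branch_present[s, b]: sample s has >=1 leaf below branch b
    branch_present = presence @ incidence.T > 0
    n = presence.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        xor = branch_present[i] ^ branch_present[i + 1 :]
        union = branch_present[i] | branch_present[i + 1 :]
        uni = xor @ lengths
        tot = union @ lengths
        if (tot == 0).any():
            j = int(np.argmax(tot == 0)) + i + 1
            raise ValueError(
                f"UniFrac undefined for pair ({table.sample_ids[i]!r}, "
                f"{table.sample_ids[j]!r}): no branch length in the union"
            )
        d[i, i + 1 :] = uni / tot
    d = d + d.T
    return DistanceMatrix(d, ids=table.sample_ids)


def distance_matrix(table: CommunityTable, metric: str = "braycurtis",
                    tree: TreeNode | None = None) -> DistanceMatrix:
    """All pairwise dissimilarities under one metric.

    ``metric``: ``braycurtis`` | ``jaccard`` | ``jaccard_binary`` |
    ``unweighted_unifrac`` (needs *tree*).
    """
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    x = table.df.to_numpy(dtype=float)
    if metric == "braycurtis":
        cond = pdist(x, metric="braycurtis")
        dm = DistanceMatrix(squareform(np.nan_to_num(cond)), ids=table.sample_ids)
    elif metric == "jaccard":
        bc = squareform(np.nan_to_num(pdist(x, metric="braycurtis")))
        dm = DistanceMatrix(2.0 * bc / (1.0 + bc), ids=table.sample_ids)
    elif metric == "jaccard_binary":
        cond = pdist(x > 0, metric="jaccard")
        dm = DistanceMatrix(squareform(np.nan_to_num(cond)), ids=table.sample_ids)
    elif metric == "unweighted_unifrac":
        if tree is None:
            raise ValueError("unweighted_unifrac requires a tree")
        dm = unweighted_unifrac(table, tree)
    else:
        raise ValueError(f"unknown beta metric {metric!r}")
    dm.metric_name = metric
    return dm
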