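"""Genome-wide hierarchical clustering and the co-clustering "molecular match".

After UNKNOWN (MFH/NOS-analogue) tumors are reclassified by the predictor,
their reclassification is validated within a dataset by asking whether each
one co-clusters with conventionally labeled samples of its predicted
subtype in an unsupervised complete-linkage dendrogram built from the
genome-wide (top-variance) expression profile, under the one minus centered
Pearson correlation distance.

"Clusters together" is operationalized deterministically: from the query's
leaf, walk up the tree to the smallest enclosing cluster containing at
least ``min_reference`` conventionally labeled samples, and take the
plurality label among those reference samples (a plurality tie yields
NONE).  This needs no tree cut and is invariant to monotone rescaling of
the heights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datasets import UNKNOWN, ExpressionDataset

NONE_LABEL = "NONE"


class ClusterError(ValueError):
    pass


@dataclass
class LinkageTree:
    linkage: np.ndarray       # scipy linkage matrix, (n-1) x 4
    leaf_ids: list            # sample ids, leaf i <-> leaf_ids[i]
    metric: str
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


@dataclass
class MatchReport:
    table: pd.DataFrame       # per query: predicted, matched, match
    match_fraction: float


def hcluster(
    ds_or_matrix,
    metric: str = "correlation",
    method: str = "complete",
) -> LinkageTree:
    """Agglomerative clustering of samples.

    ``metric`` is ``"correlation"`` (one minus centered Pearson, the
    convention for expression profiles) or ``"euclidean"`` (used for
    probability profiles).  Deterministic given input order.
    """
    if isinstance(ds_or_matrix, ExpressionDataset):
        values = ds_or_matrix.values
    else:
        values = ds_or_matrix
    X = values.to_numpy(dtype=float).T  # samples x features
    ids = list(values.columns)
    if X.shape[0] < 3:
        raise ClusterError("need at least 3 samples to cluster")
    if np.isnan(X).any():
        raise ClusterError("clustering requires imputed (complete) data")
    if metric == "correlation":
        sd = X.std(axis=1)
        if (sd == 0).any():
            bad = [ids[i] for i in np.flatnonzero(sd == 0)]
            raise ClusterError(f"constant samples under correlation metric: {bad}")
        D = pdist(X, metric="correlation")
    elif metric == "euclidean":
        D = pdist(X, metric="euclidean")
    else:
        raise ClusterError(f"unknown metric {metric!r}")
    Z = hierarchy.linkage(D, method=method)
    return LinkageTree(linkage=Z, leaf_ids=ids, metric=metric, method=method)


def _cluster_members(tree: LinkageTree):
    """Leaf sets for every node (leaves 0..n-1, internal n..2n-2)."""
    n = tree.n_leaves
    members = {i: [i] for i in range(n)}
    for k, (a, b, _, _) in enumerate(tree.linkage):
        members[n + k] = members[int(a)] + members[int(b)]
    return members


def _parents(tree: LinkageTree):
    n = tree.n_leaves
    parent = {}
    for k, (a, b, _, _) in enumerate(tree.linkage):
        parent[int(a)] = n + k
        parent[int(b)] = n + k
    return parent


def cocluster_match(
    tree: LinkageTree,
    labels: pd.Series,
    predictions: pd.Series,
    min_reference: int = 3,
) -> MatchReport:
    """Score whether reclassified samples co-cluster with their predicted class.

    ``labels`` gives the conventional label (UNKNOWN for queries) for every
    leaf; ``predictions`` gives the predicted class for exactly the UNKNOWN
    samples.
    """
    if min_reference < 1:
        raise ClusterError("min_reference must be >= 1")
    ids = tree.leaf_ids
    labels = labels.reindex(ids)
    if labels.isna().any():
        raise ClusterError("labels missing for some tree leaves")
    queries = [s for s in ids if labels[s] == UNKNOWN]
    if sorted(queries) != sorted(predictions.index):
        raise ClusterError("predictions must cover exactly the UNKNOWN samples")
    members = _cluster_members(tree)
    parent = _parents(tree)
    leaf_of = {s: i for i, s in enumerate(ids)}
    ref_labels = labels[labels != UNKNOWN]

    rows = []
    for q in queries:
        node = leaf_of[q]
        matched = NONE_LABEL
        while node in parent:
            node = parent[node]
            refs = [ids[i] for i in members[node] if labels[ids[i]] != UNKNOWN]
            if len(refs) >= min_reference:
                counts = ref_labels.loc[refs].value_counts()
                top = counts[counts == counts.max()]
                matched = top.index[0] if len(top) == 1 else NONE_LABEL
                break
        pred = predictions[q]
        rows.append((q, pred, matched, matched == pred))
    table = pd.DataFrame(rows, columns=["sample_id", "predicted", "matched", "match"])
    table = table.set_index("sample_id")
    frac = float(table["match"].mean()) if len(table) else float("nan")
    return MatchReport(table=table, match_fraction=frac)


def to_newick(tree: LinkageTree) -> str:
    """Newick string of the dendrogram with sample ids as leaf names."""
    root = hierarchy.to_tree(tree.linkage)

    def rec(node):
        if node.is_leaf():
            return tree.leaf_ids[node.id]
        left = rec(node.get_left())
        right = rec(node.get_right())
        dl = node.dist - node.get_left().dist
        dr = node.dist - node.get_right().dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return rec(root) + ";"
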