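"""Downstream association statistics and gene-set functional class scoring.

Covers the nonparametric subtype-vs-probability comparisons
(Kruskal–Wallis, Mann–Whitney), clustering of per-sample pathway
activation probability profiles into pattern clusters, the
cluster-vs-chemoresistance comparison, and gene-set (miRNA-target)
enrichment by functional class scoring (FCS) against a random-set null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .clustermatch import LinkageTree, hcluster
from .datasets import ExpressionDataset

EXACT_MW_MAX_N = 12


class StatsError(ValueError):
    pass


def kruskal_wallis(values, groups):
    """Rank-based one-way Kruskal–Wallis H with tie correction.

    Returns ``(H, p)`` with the chi-square approximation on K-1 degrees of
    freedom.  Identical values in every group give H = 0, p = 1.
    """
    arrays = [np.asarray(v, dtype=float) for v in _split(values, groups)]
    if len(arrays) < 2:
        raise StatsError("need at least two groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*arrays)
    return float(H), float(p)


def _split(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    return [values[groups == g] for g in pd.unique(groups)]


def _u_statistic(x, y):
    """Mann–Whitney U of x vs y with half credit for ties."""
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    return u


def mann_whitney(group, rest):
    """Two-sided Mann–Whitney test.

    For combined n <= 12 the p-value is exact, by enumeration of all label
    arrangements (ties handled by half-credit U); beyond that the normal
    approximation with tie and continuity correction is used.
    """
    x = np.asarray(group, dtype=float)
    y = np.asarray(rest, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise StatsError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if n1 + n2 <= EXACT_MW_MAX_N:
        pooled = np.concatenate([x, y])
        center = n1 * n2 / 2.0
        dev = abs(u_obs - center)
        total = 0
        extreme = 0
        for idx in combinations(range(n1 + n2), n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(idx)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            total += 1
            if abs(u - center) >= dev - 1e-12:
                extreme += 1
        return float(u_obs), extreme / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Pathway-pattern clusters
# ---------------------------------------------------------------------------

def cluster_profiles(profiles: pd.DataFrame, k: int = 7) -> tuple[pd.Series, LinkageTree]:
    """Cut a complete-linkage Euclidean dendrogram of probability profiles.

    ``profiles``: samples x pathways matrix of activation probabilities.
    Returns (cluster assignment per sample, tree).  Default k = 7 pattern
    clusters.
    """
    if k < 2:
        raise StatsError("k must be >= 2")
    if k > profiles.shape[0]:
        raise StatsError("k exceeds the number of samples")
    tree = hcluster(profiles.T, metric="euclidean", method="complete")
    assign = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    return pd.Series(assign, index=profiles.index), tree


def silhouette_by_k(profiles: pd.DataFrame, k_range=range(2, 11)) -> pd.Series:
    """Mean silhouette width across candidate cluster counts (transparency aid)."""
    from sklearn.metrics import silhouette_score

    out = {}
    for k in k_range:
        if k >= profiles.shape[0]:
            break
        assign, _ = cluster_profiles(profiles, k)
        if assign.nunique() < 2:
            out[k] = np.nan
            continue
        out[k] = silhouette_score(profiles.to_numpy(), assign.to_numpy())
    return pd.Series(out)


def cluster_vs_resistance(
    assignments: pd.Series,
    resistance_probs: pd.Series,
    target_clusters,
    drug: str = "",
) -> dict:
    """Mann–Whitney comparison of drug-resistance probability.

    Target clusters' samples against all other samples; reports the U
    statistic, two-sided p, direction and group medians.
    """
    target_clusters = set(np.atleast_1d(target_clusters).tolist())
    observed = set(assignments.unique())
    if not target_clusters:
        raise StatsError("empty target cluster set")
    if not target_clusters.issubset(observed):
        raise StatsError(f"unknown clusters {sorted(target_clusters - observed)}")
    probs = resistance_probs.reindex(assignments.index)
    in_mask = assignments.isin(target_clusters)
    u, p = mann_whitney(probs[in_mask], probs[~in_mask])
    med_in = float(probs[in_mask].median())
    med_out = float(probs[~in_mask].median())
    return {
        "drug": drug,
        "U": u,
        "p": p,
        "direction": "higher" if med_in > med_out else "lower",
        "median_target": med_in,
        "median_rest": med_out,
        "n_target": int(in_mask.sum()),
    }


# ---------------------------------------------------------------------------
# Functional class scoring
# ---------------------------------------------------------------------------

@dataclass
class FCSResult:
    table: pd.DataFrame       # per set: n_genes, LS, KS, p_LS, p_KS
    gene_p: pd.Series         # per-gene two-class t-test p


def _ks_uniform(p_sorted: np.ndarray) -> np.ndarray:
    """KS statistic of sorted p-values vs Uniform(0,1), vectorized on axis -1."""
    m = p_sorted.shape[-1]
    i = np.arange(1, m + 1)
    d_plus = (i / m - p_sorted).max(axis=-1)
    d_minus = (p_sorted - (i - 1) / m).max(axis=-1)
    return np.maximum(d_plus, d_minus)


def fcs_enrichment(
    ds: ExpressionDataset,
    binary_labels: pd.Series,
    gene_sets: dict,
    n_random: int = 10000,
    seed: int = 0,
) -> FCSResult:
    """Functional class scoring of gene sets against a random-set null.

    Per gene, a two-sided two-class t-test p-value is computed between the
    two label groups.  Per set, the LS statistic (mean of -ln p over
    members) and the KS statistic (max deviation of the member p-values
    from uniform) are referred to the distribution of the same statistics
    over ``n_random`` random gene sets of identical size, giving
    permutation p-values with the +1 correction.  Sets with fewer than two
    genes mapped to the data are skipped with a warning.
    """
    y = binary_labels.reindex(ds.values.columns)
    mask1 = (y == 1).to_numpy()
    if mask1.sum() < 2 or (~mask1).sum() < 2:
        raise StatsError("both classes need at least 2 samples")
    X = ds.values.to_numpy(dtype=float)
    _, p = stats.ttest_ind(X[:, mask1], X[:, ~mask1], axis=1, equal_var=True)
    p = np.nan_to_num(p, nan=1.0)
    p = np.clip(p, 1e-300, 1.0)
    gene_p = pd.Series(p, index=ds.values.index)
    neglog = -np.log(p)
    G = len(p)
    rng = np.random.default_rng(seed)

    rows = []
    for name, genes in gene_sets.items():
        idx = [i for i, g in enumerate(ds.gene_ids) if g in set(genes)]
        m = len(idx)
        if m < 2:
            warnings.warn(f"gene set {name!r} has <2 mapped genes; skipped")
            continue
        ls_obs = float(neglog[idx].mean())
        ks_obs = float(_ks_uniform(np.sort(p[idx])))
        ls_ge = 0
        ks_ge = 0
        chunk = max(1, min(n_random, 4_000_000 // max(G, 1)))
        done = 0
        while done < n_random:
            c = min(chunk, n_random - done)
            r = rng.random((c, G))
            sel = np.argpartition(r, m - 1, axis=1)[:, :m]
            ls_null = neglog[sel].mean(axis=1)
            ks_null = _ks_uniform(np.sort(p[sel], axis=1))
            ls_ge += int((ls_null >= ls_obs).sum())
            ks_ge += int((ks_null >= ks_obs).sum())
            done += c
        rows.append(
            (name, m, ls_obs, ks_obs,
             (1 + ls_ge) / (n_random + 1), (1 + ks_ge) / (n_random + 1))
        )
    table = pd.DataFrame(
        rows, columns=["set", "n_genes", "LS", "KS", "p_LS", "p_KS"]
    ).set_index("set")
    return FCSResult(table=table, gene_p=gene_p)
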