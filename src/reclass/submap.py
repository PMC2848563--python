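"""Subclass mapping: cross-dataset molecular correspondence of subtype groups.

Two independently generated expression datasets cannot be compared on
absolute values (platform and study effects dominate), but the *relative
ranking* of genes within each dataset is comparable.  Subclass mapping
asks, for every pair of candidate subclasses (a_i, b_j): are the top
marker genes of a_i (by signal-to-noise ratio against the rest of dataset
A) enriched near the top of the b_j-vs-rest ranking of dataset B, and vice
versa?  Direction-wise enrichment p-values come from permuting the other
dataset's group labels; the two directions are combined conservatively by
their maximum ("mutual enrichment"), Bonferroni-corrected across the
matrix, and thresholded into strong / weak / none verdicts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import UNKNOWN, ExpressionDataset


class SubMapError(ValueError):
    pass


@dataclass
class SubMapConfig:
    min_fraction: float = 0.10       # candidate subclass must hold >=10% of samples
    n_markers: int = 100
    n_permutations: int = 1000
    alpha_strong: float = 0.05
    alpha_weak: float = 0.10
    sd_floor_fraction: float = 0.2   # SNR sd floor as a fraction of |mean|
    combine: str = "max"             # or "fisher"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.min_fraction < 1):
            raise SubMapError("min_fraction must be in (0, 1)")
        if self.n_markers < 10:
            raise SubMapError("n_markers must be >= 10")


@dataclass
class SubMapResult:
    subclasses_a: list
    subclasses_b: list
    p_a_to_b: pd.DataFrame     # rows = A subclasses, cols = B subclasses
    p_b_to_a: pd.DataFrame     # same orientation (rows = A, cols = B)
    mutual_p: pd.DataFrame
    bonferroni_p: pd.DataFrame
    verdict: pd.DataFrame      # strong / weak / none
    config: SubMapConfig = field(repr=False, default=None)


def candidate_subclasses(labels: pd.Series, min_fraction: float = 0.10) -> list:
    """Classes holding at least ``min_fraction`` of all samples (UNKNOWN excluded)."""
    total = len(labels)
    counts = labels[labels != UNKNOWN].value_counts()
    out = sorted(c for c, n in counts.items() if n / total >= min_fraction)
    if not out:
        raise SubMapError("no candidate subclasses at this min_fraction")
    return out


def _snr(X: np.ndarray, in_mask: np.ndarray, floor_frac: float) -> np.ndarray:
    """Signal-to-noise ratio per gene: (m_in - m_out) / (s_in + s_out).

    Standard deviations are floored at ``floor_frac * |mean|`` of the
    respective group (plus a tiny absolute floor) per the classic
    marker-ranking convention.
    """
    xin, xout = X[:, in_mask], X[:, ~in_mask]
    m_in, m_out = xin.mean(axis=1), xout.mean(axis=1)
    s_in = np.maximum(xin.std(axis=1, ddof=1), floor_frac * np.abs(m_in))
    s_out = np.maximum(xout.std(axis=1, ddof=1), floor_frac * np.abs(m_out))
    denom = np.maximum(s_in + s_out, 1e-8)
    return (m_in - m_out) / denom


def snr_ranking(
    ds: ExpressionDataset,
    group_labels: pd.Series,
    target_group,
    sd_floor_fraction: float = 0.2,
) -> list:
    """Gene ids ranked descending by SNR of the target group vs the rest."""
    labels = group_labels.reindex(ds.values.columns)
    in_mask = (labels == target_group).to_numpy()
    if in_mask.sum() < 2 or (~in_mask).sum() < 2:
        raise SubMapError("target group and complement each need >= 2 samples")
    snr = _snr(ds.values.to_numpy(dtype=float), in_mask, sd_floor_fraction)
    order = np.argsort(-snr, kind="stable")
    return [ds.gene_ids[i] for i in order]


def enrichment_score(ranked_list, marker_set) -> float:
    """Unweighted KS-type running-sum enrichment score in [-1, 1].

    Walking down the ranked list, the running sum gains 1/|hits| at each
    marker and loses 1/(N - |hits|) otherwise; the score is the maximum
    deviation from zero (signed; exact magnitude ties resolve positive).
    """
    ranked = list(ranked_list)
    markers = set(marker_set)
    hits = np.fromiter((g in markers for g in ranked), dtype=bool, count=len(ranked))
    h = int(hits.sum())
    N = len(ranked)
    if h == 0:
        raise SubMapError("marker set does not intersect the ranked list")
    if h == N:
        raise SubMapError("marker set covers the whole ranked list")
    step = np.where(hits, 1.0 / h, -1.0 / (N - h))
    rs = np.cumsum(step)
    mx, mn = rs.max(), rs.min()
    # magnitude ties (within float tolerance) resolve positive
    return float(mx if mx + mn >= -1e-12 else mn)


def _es_from_positions(pos: np.ndarray, N: int, h: int) -> np.ndarray:
    """Vectorized ES from sorted hit positions.

    ``pos``: (n_cases, h) sorted 0-based hit positions.  Equivalent to
    running-sum scanning, exploiting that extrema occur at hit boundaries.
    """
    k = np.arange(h)
    after = (k + 1) / h - (pos - k) / (N - h)
    before = k / h - (pos - k) / (N - h)
    mx = after.max(axis=-1)
    mn = np.minimum(before.min(axis=-1), 0.0)
    return np.where(mx + mn >= -1e-12, mx, mn)


def _direction_p(ds_markers, labels_markers, ds_rank, labels_rank, groups_m, groups_r,
                 config: SubMapConfig, rng) -> pd.DataFrame:
    """p[marker_group, rank_group]: markers from one dataset scored in the other."""
    Xr = ds_rank.values.to_numpy(dtype=float)
    gene_index = {g: i for i, g in enumerate(ds_rank.gene_ids)}
    lab_r = labels_rank.reindex(ds_rank.values.columns)
    out = pd.DataFrame(np.nan, index=groups_m, columns=groups_r)
    # marker lists once per marker group
    markers = {}
    for a in groups_m:
        ranked = snr_ranking(ds_markers, labels_markers, a, config.sd_floor_fraction)
        markers[a] = [g for g in ranked[: config.n_markers]]
    for b in groups_r:
        in_mask = (lab_r == b).to_numpy()
        if in_mask.sum() < 2 or (~in_mask).sum() < 2:
            warnings.warn(f"group {b!r} too small; pair skipped")
            continue
        snr_obs = _snr(Xr, in_mask, config.sd_floor_fraction)
        order = np.argsort(-snr_obs, kind="stable")
        ranks = np.empty(len(order), dtype=np.int64)
        ranks[order] = np.arange(len(order))
        # permutations of the ranking dataset's labels, shared across marker groups
        n_in = int(in_mask.sum())
        G = Xr.shape[0]
        perm_ranks = np.empty((config.n_permutations, G), dtype=np.int32)
        for p in range(config.n_permutations):
            perm = np.zeros(Xr.shape[1], dtype=bool)
            perm[rng.choice(Xr.shape[1], size=n_in, replace=False)] = True
            snr_p = _snr(Xr, perm, config.sd_floor_fraction)
            o = np.argsort(-snr_p, kind="stable")
            perm_ranks[p, o] = np.arange(G, dtype=np.int32)
        for a in groups_m:
            idx = np.array([gene_index[g] for g in markers[a] if g in gene_index])
            if len(idx) == 0:
                continue
            h = len(idx)
            pos_obs = np.sort(ranks[idx])
            es_obs = _es_from_positions(pos_obs[None, :], G, h)[0]
            pos_perm = np.sort(perm_ranks[:, idx], axis=1)
            es_perm = _es_from_positions(pos_perm, G, h)
            p_val = (1 + int((es_perm >= es_obs).sum())) / (config.n_permutations + 1)
            out.loc[a, b] = p_val
    return out


def submap_matrix(
    dsA: ExpressionDataset,
    dsB: ExpressionDataset,
    config: SubMapConfig | None = None,
    labels_a: pd.Series | None = None,
    labels_b: pd.Series | None = None,
) -> SubMapResult:
    """Mutual marker-enrichment matrix between two datasets' subclasses.

    Explicit ``labels_a``/``labels_b`` allow named prediction groups (e.g.
    "MFH-LIPO") to stand in for conventional labels.  Gene sets are
    intersected first; fewer than 200 shared genes triggers a warning.
    """
    config = config or SubMapConfig()
    labels_a = dsA.labels if labels_a is None else labels_a
    labels_b = dsB.labels if labels_b is None else labels_b
    shared = [g for g in dsA.gene_ids if g in set(dsB.gene_ids)]
    if len(shared) < 3:
        raise SubMapError("too few shared genes between datasets")
    if len(shared) < 200:
        warnings.warn(f"only {len(shared)} shared genes; results may be unstable")
    A = dsA.subset_genes(shared)
    B = dsB.subset_genes(shared)
    groups_a = candidate_subclasses(labels_a.reindex(A.values.columns), config.min_fraction)
    groups_b = candidate_subclasses(labels_b.reindex(B.values.columns), config.min_fraction)
    rng = np.random.default_rng(config.seed)
    p_ab = _direction_p(A, labels_a, B, labels_b, groups_a, groups_b, config, rng)
    p_ba_t = _direction_p(B, labels_b, A, labels_a, groups_b, groups_a, config, rng)
    p_ba = p_ba_t.T  # orient rows = A subclasses
    if config.combine == "max":
        mutual = pd.DataFrame(
            np.maximum(p_ab.to_numpy(), p_ba.to_numpy()),
            index=groups_a, columns=groups_b,
        )
    elif config.combine == "fisher":
        from scipy import stats
        chi = -2 * (np.log(p_ab.to_numpy()) + np.log(p_ba.to_numpy()))
        mutual = pd.DataFrame(
            stats.chi2.sf(chi, df=4), index=groups_a, columns=groups_b
        )
    else:
        raise SubMapError(f"unknown combine rule {config.combine!r}")
    n_cells = mutual.notna().to_numpy().sum()
    bonf = (mutual * n_cells).clip(upper=1.0)
    verdict = pd.DataFrame("none", index=groups_a, columns=groups_b)
    verdict = verdict.mask(bonf < config.alpha_weak, "weak")
    verdict = verdict.mask(bonf < config.alpha_strong, "strong")
    verdict = verdict.mask(bonf.isna(), "none")
    return SubMapResult(
        subclasses_a=groups_a,
        subclasses_b=groups_b,
        p_a_to_b=p_ab,
        p_b_to_a=p_ba,
        mutual_p=mutual,
        bonferroni_p=bonf,
        verdict=verdict,
        config=config,
    )
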