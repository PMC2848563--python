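"""Bayesian probit metagene scoring of pathway activation / drug resistance.

A two-class training set (pathway experimentally ON vs control, or drug
resistant vs sensitive cell lines) defines a signature: the top-k genes by
two-class t statistic, summarized by the leading singular vector(s)
("metagene") of the gene-standardized training submatrix.  A Bayesian
probit regression of class on the metagene score(s), sampled by the
Albert–Chib latent-variable Gibbs sampler, then assigns any new sample a
posterior probability in [0, 1] of the pathway being active (or the tumor
resistant).  Probability > 0.5 is called "activated".

When the training arrays and the tumor cohort come from different
platforms/experiments, the non-biological offset between them is removed
with the empirical-Bayes batch adjustment before projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .batch import combat_adjust, estimate_batch_params
from .datasets import ExpressionDataset, merge_datasets


class ProbitError(ValueError):
    pass


@dataclass
class ProbitSignature:
    genes: list                      # selected signature genes (top k by |t|)
    t_statistic: pd.Series
    loadings: np.ndarray             # k x n_factors, orthonormal columns
    gene_mean: pd.Series             # training standardization shift
    gene_sd: pd.Series               # training standardization scale
    factor_scores: pd.DataFrame      # training samples x factors
    train_values: pd.DataFrame = field(repr=False, default=None)  # k x n (raw)
    train_labels: pd.Series = field(repr=False, default=None)
    n_factors: int = 1


@dataclass
class ActivationProfile:
    probability: pd.Series
    sd: pd.Series
    call: pd.Series                  # probability > 0.5
    shared_gene_fraction: float = 1.0


def build_signature(
    train_ds: ExpressionDataset,
    binary_labels: pd.Series,
    k_genes: int = 100,
    n_factors: int = 1,
) -> ProbitSignature:
    """Select signature genes and factorize the training submatrix.

    ``binary_labels`` maps each training sample to 0/1 (control/ON).  Both
    classes need at least 3 samples.
    """
    y = binary_labels.reindex(train_ds.values.columns).astype(int)
    if set(y.unique()) != {0, 1}:
        raise ProbitError("binary_labels must contain exactly the values 0 and 1")
    if (y == 0).sum() < 3 or (y == 1).sum() < 3:
        raise ProbitError("each class needs at least 3 training samples")
    X = train_ds.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ProbitError("training data must be complete")
    mask1 = (y == 1).to_numpy()
    t, _ = stats.ttest_ind(X[:, mask1], X[:, ~mask1], axis=1, equal_var=True)
    t = np.nan_to_num(t, nan=0.0)
    if k_genes > train_ds.n_genes:
        warnings.warn("k_genes exceeds gene count; clipping")
        k_genes = train_ds.n_genes
    order = np.argsort(-np.abs(t), kind="stable")[:k_genes]
    order = np.sort(order)  # keep matrix row order
    genes = [train_ds.gene_ids[i] for i in order]
    sub = X[order]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    sd = np.where(sd < 1e-8, 1e-8, sd)
    Z = (sub - mean[:, None]) / sd[:, None]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = U[:, :n_factors]
    scores = loadings.T @ Z  # factors x samples
    return ProbitSignature(
        genes=genes,
        t_statistic=pd.Series(t[order], index=genes),
        loadings=loadings,
        gene_mean=pd.Series(mean, index=genes),
        gene_sd=pd.Series(sd, index=genes),
        factor_scores=pd.DataFrame(
            scores.T, index=train_ds.values.columns,
            columns=[f"factor{i+1}" for i in range(n_factors)],
        ),
        train_values=train_ds.values.iloc[order].copy(),
        train_labels=y,
        n_factors=n_factors,
    )


def fit_probit(
    factor_scores,
    binary_labels,
    n_iter: int = 5000,
    burn_in: int = 1000,
    seed: int = 0,
    prior_sd: float = 10.0,
) -> np.ndarray:
    """Albert–Chib Gibbs sampler for Bayesian probit regression.

    Latent normal variables truncated by the class label alternate with
    conjugate normal draws of the coefficients (intercept + one per
    factor), under independent N(0, prior_sd^2) priors.  Returns the
    post-burn-in coefficient draws, shape (n_iter - burn_in, 1 + n_factors).
    """
    S = np.asarray(factor_scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    y = np.asarray(binary_labels, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ProbitError("labels must be binary 0/1")
    if not np.all(np.isfinite(S)):
        raise ProbitError("factor scores must be finite")
    n, f = S.shape
    W = np.column_stack([np.ones(n), S])
    rng = np.random.default_rng(seed)
    prec = W.T @ W + np.eye(f + 1) / prior_sd**2
    V = np.linalg.inv(prec)
    L = np.linalg.cholesky(V)
    beta = np.zeros(f + 1)
    draws = np.empty((n_iter - burn_in, f + 1))
    lo = np.where(y == 1, 0.0, -np.inf)
    hi = np.where(y == 1, np.inf, 0.0)
    for it in range(n_iter):
        mu = W @ beta
        # truncated-normal latent draws via inverse-CDF
        a = stats.norm.cdf(lo - mu)
        b = stats.norm.cdf(hi - mu)
        u = rng.uniform(a, b)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        z = mu + stats.norm.ppf(u)
        m = V @ (W.T @ z)
        beta = m + L @ rng.standard_normal(f + 1)
        if it >= burn_in:
            draws[it - burn_in] = beta
    return draws


def posterior_probability(draws: np.ndarray, scores) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and sd of P(active) = Phi(b0 + b . score) per sample."""
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    W = np.column_stack([np.ones(S.shape[0]), S])
    lin = W @ draws.T  # samples x draws
    probs = stats.norm.cdf(lin)
    return probs.mean(axis=1), probs.std(axis=1, ddof=1)


def score_samples(
    signature: ProbitSignature,
    posterior_draws: np.ndarray,
    test_ds: ExpressionDataset,
    adjust: str = "none",
) -> ActivationProfile:
    """Posterior activation probability for each test sample.

    With ``adjust="combat"`` the training submatrix and the test values on
    the shared signature genes are pooled, adjusted for their
    train-vs-test batch offset, and the standardization re-derived from
    the adjusted training half before projecting onto the metagene.
    At least half of the signature genes must be present in the test data.
    """
    if adjust not in ("none", "combat"):
        raise ProbitError(f"unknown adjust mode {adjust!r}")
    shared = [g for g in signature.genes if g in set(test_ds.gene_ids)]
    frac = len(shared) / len(signature.genes)
    if frac < 0.5:
        raise ProbitError(
            f"only {frac:.0%} of signature genes present in test data (<50%)"
        )
    keep = [i for i, g in enumerate(signature.genes) if g in set(shared)]
    loadings = signature.loadings[keep]
    test_vals = test_ds.values.loc[shared]

    if adjust == "combat":
        train = ExpressionDataset(
            values=signature.train_values.loc[shared],
            labels=pd.Series("UNKNOWN", index=signature.train_values.columns),
            batch=pd.Series("train", index=signature.train_values.columns),
        )
        test = ExpressionDataset(
            values=test_vals,
            labels=pd.Series("UNKNOWN", index=test_vals.columns),
            batch=pd.Series("test", index=test_vals.columns),
        )
        merged = merge_datasets([train, test])
        params = estimate_batch_params(merged)
        adjusted = combat_adjust(merged, params)
        adj_train = adjusted.values[list(train.sample_ids)]
        adj_test = adjusted.values[list(test.sample_ids)]
        mean = adj_train.mean(axis=1).to_numpy()
        sd = adj_train.std(axis=1, ddof=1).to_numpy()
        sd = np.where(sd < 1e-8, 1e-8, sd)
        Z = (adj_test.to_numpy(dtype=float) - mean[:, None]) / sd[:, None]
    else:
        mean = signature.gene_mean.loc[shared].to_numpy()
        sd = signature.gene_sd.loc[shared].to_numpy()
        Z = (test_vals.to_numpy(dtype=float) - mean[:, None]) / sd[:, None]

    scores = (loadings.T @ Z).T  # samples x factors
    prob, sd_p = posterior_probability(posterior_draws, scores)
    idx = test_vals.columns
    probability = pd.Series(prob, index=idx)
    return ActivationProfile(
        probability=probability,
        sd=pd.Series(sd_p, index=idx),
        call=probability > 0.5,
        shared_gene_fraction=frac,
    )


def train_and_score(
    train_ds: ExpressionDataset,
    binary_labels: pd.Series,
    test_ds: ExpressionDataset,
    k_genes: int = 100,
    n_factors: int = 1,
    n_iter: int = 5000,
    burn_in: int = 1000,
    seed: int = 0,
    adjust: str = "combat",
) -> tuple[ProbitSignature, np.ndarray, ActivationProfile]:
    """Convenience wrapper: build signature, fit probit, score a cohort."""
    sig = build_signature(train_ds, binary_labels, k_genes, n_factors)
    y = sig.train_labels.to_numpy()
    draws = fit_probit(sig.factor_scores.to_numpy(), y, n_iter, burn_in, seed)
    profile = score_samples(sig, draws, test_ds, adjust=adjust)
    return sig, draws, profile
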