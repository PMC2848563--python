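import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reclass import (
    build_signature,
    fit_probit,
    generate_cohort,
    generate_pathway_training,
    score_samples,
    train_and_score,
)
from reclass.probit import ProbitError, posterior_probability

from conftest import make_dataset


def quadrature_posterior_probability(scores, y, at_score, prior_sd=10.0, grid_n=401):
    """2-D grid quadrature of the probit posterior; P(y=1 | at_score)."""
    g = np.linspace(-35, 35, grid_n)
    B0, B1 = np.meshgrid(g, g, indexing="ij")
    loglik = np.zeros_like(B0)
    for s, yi in zip(scores, y):
        lin = B0 + B1 * s
        p = stats.norm.cdf(lin if yi == 1 else -lin)
        loglik += np.log(np.clip(p, 1e-300, 1))
    logpost = (
        loglik
        + stats.norm.logpdf(B0, 0, prior_sd)
        + stats.norm.logpdf(B1, 0, prior_sd)
    )
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    return float((w * stats.norm.cdf(B0 + B1 * at_score)).sum())


def two_class_training(rng, n_per_arm=10, n_genes=60, n_signal=15, effect=2.0):
    y = np.array([0] * n_per_arm + [1] * n_per_arm)
    X = rng.normal(size=(n_genes, 2 * n_per_arm))
    X[:n_signal, y == 1] += effect
    ds = make_dataset(X)
    return ds, pd.Series(y, index=ds.sample_ids)


class TestBuildSignature:
    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(0)
        ds, y = two_class_training(rng)
        s1 = build_signature(ds, y)
        s2 = build_signature(ds, 1 - y)
        assert s1.genes == s2.genes
        np.testing.assert_allclose(s1.t_statistic.to_numpy(),
                                   -s2.t_statistic.to_numpy())
        np.testing.assert_allclose(np.abs(s1.loadings), np.abs(s2.loadings))

    def test_rank_one_data_recovers_generating_scores(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=20)
        v = rng.normal(size=12)
        X = np.outer(u, v)
        ds = make_dataset(X)
        y = pd.Series((v > np.median(v)).astype(int), index=ds.sample_ids)
        sig = build_signature(ds, y, k_genes=20, n_factors=1)
        z = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        # factor scores proportional to the generating sample scores v (centered)
        got = sig.factor_scores.iloc[:, 0].to_numpy()
        ref = z.T @ (u / np.linalg.norm(u))
        corr = abs(np.corrcoef(got, ref)[0, 1])
        assert corr > 0.999

    def test_planted_direction_recovered(self):
        rng = np.random.default_rng(2)
        ds, y = two_class_training(rng, n_per_arm=20, effect=2.5)
        sig = build_signature(ds, y, k_genes=30)
        direction = np.array([1.0] * 15 + [0.0] * 15)[
            [int(g[1:]) for g in sig.genes]
        ] if False else None
        signal = np.array([1.0 if int(g[1:]) < 15 else 0.0 for g in sig.genes])
        corr = abs(np.corrcoef(sig.loadings[:, 0], signal)[0, 1])
        assert corr >= 0.9

    def test_requires_binary_labels(self):
        rng = np.random.default_rng(3)
        ds, y = two_class_training(rng)
        with pytest.raises(ProbitError):
            build_signature(ds, y + 1)

    def test_k_clipped_with_warning(self):
        rng = np.random.default_rng(4)
        ds, y = two_class_training(rng, n_genes=20)
        with pytest.warns(UserWarning, match="clip"):
            sig = build_signature(ds, y, k_genes=500)
        assert len(sig.genes) == 20


class TestFitProbit:
    def test_matches_quadrature_oracle_on_1d_toy(self):
        scores = np.array([-1.0, -1.0, 1.0, 1.0])
        y = np.array([0, 0, 1, 1])
        oracle = quadrature_posterior_probability(scores, y, at_score=1.0)
        draws = fit_probit(scores, y, n_iter=12000, burn_in=2000, seed=7)
        gibbs = float(stats.norm.cdf(draws @ np.array([1.0, 1.0])).mean())
        assert gibbs == pytest.approx(oracle, abs=0.02)

    def test_null_slope_interval_covers_zero(self):
        rng = np.random.default_rng(5)
        covered = 0
        for rep in range(20):
            scores = rng.normal(size=40)
            y = rng.integers(0, 2, size=40)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            draws = fit_probit(scores, y, n_iter=1500, burn_in=300,
                               seed=int(rng.integers(1 << 30)))
            lo, hi = np.percentile(draws[:, 1], [2.5, 97.5])
            covered += int(lo <= 0 <= hi)
        assert covered >= 18

    def test_seeded_determinism(self):
        scores = np.array([-1.0, -0.5, 0.5, 1.0])
        y = np.array([0, 0, 1, 1])
        d1 = fit_probit(scores, y, n_iter=500, burn_in=100, seed=3)
        d2 = fit_probit(scores, y, n_iter=500, burn_in=100, seed=3)
        np.testing.assert_array_equal(d1, d2)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ProbitError):
            fit_probit(np.zeros(4), np.array([0, 1, 2, 1]))

    def test_posterior_probability_monotone_in_score(self):
        scores = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        draws = fit_probit(scores, y, n_iter=2000, burn_in=500, seed=1)
        grid = np.linspace(-3, 3, 13)
        probs, _ = posterior_probability(draws, grid)
        assert np.all(np.diff(probs) > 0)


class TestScoreSamples:
    def test_duplicated_training_sample_scores_high(self):
        rng = np.random.default_rng(6)
        ds, y = two_class_training(rng, n_per_arm=12, effect=2.5)
        sig = build_signature(ds, y, k_genes=30)
        draws = fit_probit(sig.factor_scores.to_numpy(), y.to_numpy(), seed=2)
        on_sample = ds.values.loc[sig.genes, [ds.sample_ids[-1]]]
        probe = make_dataset(on_sample.to_numpy(), sample_prefix="Q",
                             gene_prefix="")
        probe.values.index = on_sample.index
        profile = score_samples(sig, draws, probe, adjust="none")
        assert profile.probability.iloc[0] > 0.9
        assert profile.call.iloc[0]

    def test_boundary_score_is_uncertain_and_uncalled(self):
        # antisymmetric design with class overlap: the posterior is exactly
        # symmetric under sign flip, so P(active | score=0) = 1/2
        scores = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = np.array([0, 1, 0, 1, 0, 1])
        draws = fit_probit(scores, y, n_iter=6000, burn_in=1000, seed=4)
        prob, _ = posterior_probability(draws, np.array([0.0]))
        assert prob[0] == pytest.approx(0.5, abs=0.05)

    def test_insufficient_gene_overlap_rejected(self, default_cohort):
        ds, _ = default_cohort
        rng = np.random.default_rng(7)
        train, y = generate_pathway_training(pathway_id="SRC", seed=11)
        sig = build_signature(train, y)
        draws = fit_probit(sig.factor_scores.to_numpy(), y.to_numpy(),
                           n_iter=600, burn_in=100, seed=1)
        keep = [g for g in ds.gene_ids if g not in set(sig.genes[:60])]
        with pytest.raises(ProbitError, match="50%"):
            score_samples(sig, draws, ds.subset_genes(keep))

    def test_probabilities_invariant_to_genewise_affine_rescaling(self, default_cohort):
        ds, truth = default_cohort
        train, y = generate_pathway_training(pathway_id="SRC", seed=11)
        sig, draws, prof = train_and_score(
            train, y, ds, n_iter=2000, burn_in=400, seed=5, adjust="combat"
        )
        rng = np.random.default_rng(8)
        scaled = ds.copy()
        a = rng.uniform(0.5, 2.0, size=ds.n_genes)
        b = rng.normal(0, 1.0, size=ds.n_genes)
        scaled.values.iloc[:, :] = ds.values.to_numpy() * a[:, None] + b[:, None]
        prof2 = score_samples(sig, draws, scaled, adjust="combat")
        diff = np.abs(prof.probability - prof2.probability)
        assert float(diff.mean()) < 0.05

    def test_slope_sign_recovery_across_seeds(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            ds, y = two_class_training(rng, n_per_arm=12, effect=2.0)
            sig = build_signature(ds, y, k_genes=30)
            draws = fit_probit(sig.factor_scores.to_numpy(), y.to_numpy(),
                               n_iter=800, burn_in=200, seed=rep)
            slope = draws[:, 1].mean()
            # sign convention follows the SVD; compare against the ON-arm mean score
            on_mean = sig.factor_scores.to_numpy()[y.to_numpy() == 1].mean()
            hits += int(np.sign(slope) == np.sign(on_mean))
        assert hits == 20
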