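import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from reclass import (
    SyntheticConfig,
    TwoStepConfig,
    f_select,
    fit_centroids,
    fit_two_step,
    generate_cohort,
    loocv,
    permutation_test,
    port_model,
    predict,
    predict_two_step,
)
from reclass.centroid import (
    ClassifierError,
    _select_fold,
    two_step_from_dict,
    two_step_to_dict,
)

from conftest import make_dataset


def brute_force_nearest(values, centroids, metric="centered_correlation"):
    """Independent per-sample argmin over explicit distance computation."""
    calls = {}
    for s in values.columns:
        x = values[s].to_numpy()
        dists = {}
        for c in centroids.columns:
            m = centroids[c].to_numpy()
            if metric == "euclidean":
                dists[c] = float(np.sqrt(((x - m) ** 2).sum()))
            else:
                dists[c] = float(1 - np.corrcoef(x, m)[0, 1])
        calls[s] = min(sorted(dists), key=lambda c: dists[c])
    return calls


class TestFSelect:
    def test_constant_gene_excluded(self):
        x = np.array([[5.0] * 6, [1, 2, 3, 7, 8, 9.0]])
        ds = make_dataset(x, ["LEIO"] * 3 + ["LIPO"] * 3)
        with pytest.warns(UserWarning, match="constant"):
            sel = f_select(ds, p_threshold=0.5)
        assert "G0" in sel.excluded
        assert "G0" not in sel.genes

    def test_two_class_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 6))
        ds = make_dataset(x, ["LEIO"] * 3 + ["LIPO"] * 3)
        sel = f_select(ds, p_threshold=1.0)
        t, _ = stats.ttest_ind(x[:, :3], x[:, 3:], axis=1, equal_var=True)
        np.testing.assert_allclose(sel.f_statistic.to_numpy(), t**2, rtol=1e-10)

    def test_selection_sorted_by_ascending_p(self):
        ds, _ = generate_cohort(seed=1)
        sel = f_select(ds, p_threshold=1e-3)
        ps = sel.p_value.loc[sel.genes].to_numpy()
        assert np.all(np.diff(ps) >= 0)

    def test_small_class_rejected(self):
        ds = make_dataset(np.random.default_rng(1).normal(size=(3, 4)),
                          ["LEIO", "LEIO", "LEIO", "LIPO"])
        with pytest.raises(ClassifierError, match="LIPO"):
            f_select(ds)

    def test_default_step1_threshold(self):
        assert TwoStepConfig().step1_p == 4e-7


class TestCentroidsAndPredict:
    def test_singleton_classes_reproduce_samples(self):
        x = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        ds = make_dataset(x, ["LEIO", "LIPO"])
        model = fit_centroids(ds, ds.gene_ids)
        np.testing.assert_array_equal(model.centroids["LEIO"].to_numpy(), x[:, 0])
        np.testing.assert_array_equal(model.centroids["LIPO"].to_numpy(), x[:, 1])

    def test_class_mean(self):
        ds = make_dataset([[0, 2, 9], [0, 2, 9]], ["LEIO", "LEIO", "LIPO"])
        model = fit_centroids(ds, ds.gene_ids)
        assert model.centroids["LEIO"].tolist() == [1, 1]

    def test_centroids_match_brute_force_means(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 12))
        labels = ["LEIO", "LIPO", "FIBRO"] * 4
        ds = make_dataset(x, labels)
        model = fit_centroids(ds, ds.gene_ids)
        for c in ("LEIO", "LIPO", "FIBRO"):
            cols = [j for j, l in enumerate(labels) if l == c]
            np.testing.assert_allclose(
                model.centroids[c].to_numpy(), x[:, cols].mean(axis=1)
            )

    def test_sample_equal_to_centroid_is_assigned_to_it(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 4))
        ds = make_dataset(x, ["LEIO", "LEIO", "LIPO", "LIPO"])
        model = fit_centroids(ds, ds.gene_ids)
        probe = make_dataset(model.centroids[["LIPO"]].to_numpy())
        res = predict(model, probe)
        assert res.predicted.iloc[0] == "LIPO"
        assert res.distances_step1.iloc[0]["LIPO"] == pytest.approx(0, abs=1e-12)
        assert res.margin.iloc[0] > 0

    def test_anticorrelated_sample_goes_to_matching_class(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        model = fit_centroids(
            make_dataset(np.column_stack([a, -a]), ["LEIO", "LIPO"]),
            [f"G{i}" for i in range(4)],
        )
        res = predict(model, make_dataset(a[:, None]))
        # sample identical to LEIO centroid (distance 0) vs anti-correlated LIPO
        assert res.predicted.iloc[0] == "LEIO"
        assert res.distances_step1.iloc[0]["LIPO"] == pytest.approx(2.0)

    def test_assignments_match_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(8, 9))
        labels = ["LEIO", "LIPO", "FIBRO"] * 3
        ds = make_dataset(x, labels)
        model = fit_centroids(ds, ds.gene_ids)
        probes = make_dataset(rng.normal(size=(8, 5)), sample_prefix="Q")
        res = predict(model, probes)
        oracle = brute_force_nearest(probes.values, model.centroids)
        assert dict(res.predicted) == oracle

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arrays(float, (6, 3), elements=st.floats(-10, 10)),
        st.floats(0.1, 5),
        st.floats(-20, 20),
    )
    def test_correlation_metric_affine_invariant(self, x, a, b):
        ds = make_dataset(x, ["LEIO", "LIPO", "FIBRO"])
        if np.any(np.ptp(x, axis=0) < 1e-6):
            return  # near-constant columns make correlation degenerate
        model = fit_centroids(ds, ds.gene_ids)
        probe = np.random.default_rng(0).normal(size=(6, 2))
        r1 = predict(model, make_dataset(probe))
        r2 = predict(model, make_dataset(a * probe + b))
        clear = r1.margin > 1e-6  # float noise can flip exact ties
        assert r1.predicted[clear].tolist() == r2.predicted[clear].tolist()
        np.testing.assert_allclose(
            r1.distances_step1.to_numpy(), r2.distances_step1.to_numpy(), atol=1e-7
        )


class TestTwoStep:
    def test_missing_class_rejected(self):
        ds, _ = generate_cohort(seed=5)
        keep = ds.labels.index[ds.labels != "MPNST"]
        with pytest.raises(ClassifierError, match="MPNST"):
            fit_two_step(ds.subset_samples(keep))

    def test_union_gene_count_bounds(self, default_cohort):
        ds, _ = default_cohort
        model = fit_two_step(ds)
        n1, n2 = len(model.step1.genes), len(model.step2.genes)
        assert model.n_union_genes <= n1 + n2
        overlap = set(model.step1.genes) & set(model.step2.genes)
        assert model.n_union_genes == n1 + n2 - len(overlap)

    def test_two_step_prediction_matches_two_stage_oracle(self, default_cohort):
        ds, _ = default_cohort
        model = fit_two_step(ds)
        sub = ds.subset_samples(ds.sample_ids[::6])
        res = predict_two_step(model, sub)
        step1 = brute_force_nearest(sub.values.loc[model.step1.genes],
                                    model.step1.centroids)
        for s, c1 in step1.items():
            if c1 == "COMPOSITE":
                step2 = brute_force_nearest(
                    sub.values.loc[model.step2.genes, [s]], model.step2.centroids
                )
                assert res.predicted[s] == step2[s]
                assert res.step_path[s] == "1->2"
            else:
                assert res.predicted[s] == c1
                assert res.step_path[s] == "1"

    def test_non_composite_calls_equal_step1_model(self, default_cohort):
        ds, _ = default_cohort
        model = fit_two_step(ds)
        res1 = predict(model.step1, ds)
        res2 = predict_two_step(model, ds)
        non_comp = res1.predicted.index[res1.predicted != "COMPOSITE"]
        assert res1.predicted.loc[non_comp].equals(res2.predicted.loc[non_comp])

    def test_serialization_roundtrip(self, default_cohort):
        ds, _ = default_cohort
        model = fit_two_step(ds)
        back = two_step_from_dict(json.loads(json.dumps(two_step_to_dict(model))))
        pd.testing.assert_frame_equal(back.step1.centroids, model.step1.centroids)
        assert back.step2.genes == model.step2.genes


class TestCrossValidation:
    def separated_dataset(self):
        # disjoint value ranges per class over every gene
        rng = np.random.default_rng(6)
        sizes = {"SYN": 5, "LEIO": 5, "LIPO": 5, "MPNST": 5, "FIBRO": 5, "RHAB": 5}
        cfg = SyntheticConfig(
            n_genes=300, marker_block_size=10, composite_block_size=10,
            pathway_block_size=10, let7_set_size=10, null_set_size=10,
            class_sizes=sizes, n_unknown=0, marker_effect=6.0, noise_sd=0.3,
        )
        return generate_cohort(cfg, seed=int(rng.integers(1 << 30)))[0]

    def test_perfectly_separated_classes_give_accuracy_one(self):
        report = loocv(self.separated_dataset())
        assert report.accuracy == 1.0

    def test_confusion_trace_consistency(self, default_cohort):
        ds, _ = default_cohort
        report = loocv(ds)
        assert report.accuracy == pytest.approx(
            np.trace(report.confusion.to_numpy()) / report.n
        )
        assert ((report.sensitivity.dropna() >= 0) & (report.sensitivity.dropna() <= 1)).all()

    def test_null_labels_give_chance_accuracy(self, null_config):
        ds, _ = generate_cohort(null_config, seed=13)
        report = loocv(ds, TwoStepConfig(fallback_n_genes=10))
        # 6 balanced classes: chance is ~1/6; binomial 99% envelope for n=36
        assert report.accuracy < 0.40

    def test_held_out_sample_never_influences_selection(self, null_config):
        cfg = SyntheticConfig(**{**null_config.__dict__, "marker_effect": 3.0})
        ds, _ = generate_cohort(cfg, seed=14)
        X = ds.values.to_numpy().copy()
        labels = ds.labels.to_numpy()
        lab1 = np.where(np.isin(labels, ("MPNST", "SYN")), "COMPOSITE", labels)
        cols = np.arange(1, ds.n_samples)  # fold holding out sample 0
        sel_before, _, _ = _select_fold(X, cols, lab1[1:], 4e-7, 10)
        X[:, 0] = 1e6  # poison the held-out sample
        sel_after, _, _ = _select_fold(X, cols, lab1[1:], 4e-7, 10)
        np.testing.assert_array_equal(sel_before, sel_after)

    def test_fixed_gene_list_mode_runs(self, null_config):
        cfg = SyntheticConfig(**{**null_config.__dict__, "marker_effect": 4.0})
        ds, _ = generate_cohort(cfg, seed=15)
        report = loocv(ds, TwoStepConfig(reselect_in_cv=False, fallback_n_genes=10))
        assert 0.0 <= report.accuracy <= 1.0


class TestPermutationTest:
    def test_p_floor_when_observed_beats_all_permutations(self, null_config):
        cfg = SyntheticConfig(**{**null_config.__dict__, "marker_effect": 6.0})
        ds, _ = generate_cohort(cfg, seed=16)
        p = permutation_test(ds, TwoStepConfig(fallback_n_genes=10),
                             n_perm=99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_seed_reproducibility(self, null_config):
        ds, _ = generate_cohort(null_config, seed=17)
        cfg = TwoStepConfig(fallback_n_genes=10)
        p1 = permutation_test(ds, cfg, n_perm=19, seed=5)
        p2 = permutation_test(ds, cfg, n_perm=19, seed=5)
        assert p1 == p2

    def test_minimum_permutations_enforced(self, null_config):
        ds, _ = generate_cohort(null_config, seed=18)
        with pytest.raises(ClassifierError):
            permutation_test(ds, TwoStepConfig(fallback_n_genes=10), n_perm=5)


class TestPortModel:
    def test_full_overlap_keeps_gene_list(self, default_cohort):
        ds, _ = default_cohort
        model = fit_two_step(ds)
        target, _ = generate_cohort(seed=21, batch_name="D2")
        ported, report = port_model(model, target)
        assert ported.step1.genes == model.step1.genes
        assert report.lost_step1 == [] and report.lost_step2 == []

    def test_missing_genes_reported(self, default_cohort):
        ds, _ = default_cohort
        model = fit_two_step(ds)
        target, _ = generate_cohort(seed=22, batch_name="D2")
        drop = model.step1.genes[:2]
        target = target.subset_genes([g for g in target.gene_ids if g not in drop])
        ported, report = port_model(model, target)
        assert sorted(report.lost_step1) == sorted(drop)
        assert len(ported.step1.genes) == len(model.step1.genes) - 2

    def test_port_to_batch_shifted_copy_preserves_predictions(self, default_cohort):
        ds, truth = default_cohort
        model = fit_two_step(ds)
        rng = np.random.default_rng(23)
        shifted = ds.copy()
        shift = rng.normal(0, 0.5, size=ds.n_genes)
        shifted.values.iloc[:, :] = ds.values.to_numpy() + shift[:, None]
        ported, _ = port_model(model, shifted)
        res_orig = predict_two_step(model, ds)
        res_port = predict_two_step(ported, shifted)
        agreement = (res_orig.predicted == res_port.predicted).mean()
        assert agreement >= 0.95
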