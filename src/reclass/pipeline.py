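"""End-to-end orchestration of the reclassification analysis.

The pipeline follows the study design: train the two-step predictor on
the first (training) dataset, cross-validate it (optionally with a
permutation test), reclassify UNKNOWN samples everywhere (porting the
model to other datasets), validate the reclassification within datasets
by co-clustering and across datasets by subclass mapping, score oncogenic
pathway activation per sample with the probit framework, cluster the
activation profiles and test cluster-vs-chemoresistance associations,
and finally run gene-set functional class scoring on the
pathway-stratified cohort.  Every stage writes a machine-readable
artifact and the run report echoes the configuration verbatim.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .centroid import (
    TwoStepConfig, fit_two_step, loocv, permutation_test, port_model,
    predict_two_step, two_step_to_dict,
)
from .clustermatch import cocluster_match, hcluster
from .datasets import UNKNOWN, median_center_samples, read_expression_table, variance_filter
from .probit import train_and_score
from .simulate import PATHWAYS, LET7_PATHWAY, SyntheticConfig, generate_multi_dataset, generate_pathway_training, make_gene_sets
from .stats import cluster_profiles, cluster_vs_resistance, fcs_enrichment
from .submap import SubMapConfig, submap_matrix

log = logging.getLogger("reclass")


class ConfigError(ValueError):
    pass


REQUIRED_FIELDS = ("seed", "output_dir")


def validate_config(config: dict) -> None:
    """Schema check before any compute; names the offending field."""
    for f in REQUIRED_FIELDS:
        if f not in config:
            raise ConfigError(f"config missing required field: {f!r}")
    if "simulate" not in config and "datasets" not in config:
        raise ConfigError("config must provide either 'simulate' or 'datasets'")


def _load_datasets(config: dict):
    """Returns (list of datasets, optional list of truth tables)."""
    if "simulate" in config:
        sim = config["simulate"] or {}
        overrides = sim.get("overrides", {})
        syn = SyntheticConfig(**overrides)
        pairs = generate_multi_dataset(
            syn,
            n_datasets=int(sim.get("n_datasets", 2)),
            seed=int(config["seed"]),
            gene_keep_fraction=float(sim.get("gene_keep_fraction", 0.9)),
        )
        return [p[0] for p in pairs], [p[1] for p in pairs], syn
    datasets = []
    for entry in config["datasets"]:
        datasets.append(read_expression_table(entry["matrix"], entry["annotation"]))
    return datasets, None, None


def run_pipeline(config: dict) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    validate_config(config)
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    report = {"version": __version__, "config": config, "stages": {}}

    datasets, truths, syn = _load_datasets(config)
    datasets = [median_center_samples(ds) for ds in datasets]
    train_ds = datasets[0]

    # --- stage 1: train two-step model -------------------------------------
    clf_cfg = TwoStepConfig(**(config.get("classifier") or {}))
    model = fit_two_step(train_ds, clf_cfg)
    model_path = out / "model.json"
    model_path.write_text(json.dumps(two_step_to_dict(model), indent=1))
    report["stages"]["model"] = {
        "path": str(model_path),
        "n_step1_genes": len(model.step1.genes),
        "n_step2_genes": len(model.step2.genes),
        "n_union_genes": model.n_union_genes,
    }
    log.info("trained two-step model: %d union genes", model.n_union_genes)

    # --- stage 2: cross-validation ------------------------------------------
    cv = loocv(train_ds, clf_cfg)
    n_perm = int(config.get("permutations", 0))
    if n_perm:
        cv.permutation_p = permutation_test(
            train_ds, clf_cfg, n_perm=n_perm, seed=seed,
            observed_accuracy=cv.accuracy,
        )
    cv_path = out / "cv_report.json"
    cv_path.write_text(json.dumps({
        "accuracy": cv.accuracy,
        "n": cv.n,
        "permutation_p": cv.permutation_p,
        "confusion": cv.confusion.to_dict(),
        "sensitivity": cv.sensitivity.to_dict(),
        "specificity": cv.specificity.to_dict(),
    }, indent=1))
    report["stages"]["cross_validation"] = {
        "path": str(cv_path), "accuracy": cv.accuracy, "permutation_p": cv.permutation_p,
    }
    log.info("LOOCV accuracy %.3f (permutation p=%s)", cv.accuracy, cv.permutation_p)

    # --- stage 3: reclassify UNKNOWN samples --------------------------------
    predictions = {}
    for i, ds in enumerate(datasets):
        unknown = ds.labels.index[ds.labels == UNKNOWN]
        if len(unknown) == 0:
            continue
        if i == 0:
            use_model = model
        else:
            use_model, _ = port_model(model, ds, clf_cfg)
        res = predict_two_step(use_model, ds.subset_samples(unknown))
        predictions[i] = res.predicted
    pred_rows = []
    for i, pred in predictions.items():
        for s, c in pred.items():
            pred_rows.append((s, list(pd.unique(datasets[i].batch))[0], c))
    pred_tab = pd.DataFrame(pred_rows, columns=["sample_id", "dataset", "predicted"])
    pred_path = out / "predictions.tsv"
    pred_tab.to_csv(pred_path, sep="\t", index=False)
    report["stages"]["reclassification"] = {
        "path": str(pred_path), "n_reclassified": len(pred_tab),
        "class_counts": pred_tab["predicted"].value_counts().to_dict(),
    }

    # --- stage 4: co-clustering molecular match -----------------------------
    match_cfg = config.get("match") or {}
    top_fraction = float(match_cfg.get("top_fraction", 1 / 3))
    min_reference = int(match_cfg.get("min_reference", 3))
    match_tables = []
    for i, ds in enumerate(datasets):
        if i not in predictions:
            continue
        filtered = variance_filter(ds, top_fraction)
        tree = hcluster(filtered, metric="correlation", method="complete")
        mr = cocluster_match(tree, ds.labels, predictions[i], min_reference)
        tab = mr.table.copy()
        tab["dataset"] = list(pd.unique(ds.batch))[0]
        match_tables.append(tab)
    match_tab = pd.concat(match_tables) if match_tables else pd.DataFrame()
    match_path = out / "match_report.tsv"
    match_tab.to_csv(match_path, sep="\t")
    match_fraction = float(match_tab["match"].mean()) if len(match_tab) else None
    report["stages"]["cocluster_match"] = {
        "path": str(match_path), "match_fraction": match_fraction,
    }
    log.info("co-cluster match fraction: %s", match_fraction)

    # --- stage 5: subclass mapping across datasets --------------------------
    if len(datasets) >= 2:
        sm_cfg = SubMapConfig(**{**{"seed": seed}, **(config.get("submap") or {})})
        sm = submap_matrix(datasets[0], datasets[1], sm_cfg)
        sm_path = out / "submap.tsv"
        sm.bonferroni_p.to_csv(sm_path, sep="\t")
        (out / "submap.json").write_text(json.dumps({
            "subclasses_a": sm.subclasses_a,
            "subclasses_b": sm.subclasses_b,
            "mutual_p": sm.mutual_p.to_dict(),
            "bonferroni_p": sm.bonferroni_p.to_dict(),
            "verdict": sm.verdict.to_dict(),
            "n_permutations": sm_cfg.n_permutations,
        }, indent=1))
        diag = [
            sm.verdict.loc[c, c]
            for c in sm.subclasses_a if c in sm.verdict.columns
        ]
        report["stages"]["submap"] = {
            "path": str(sm_path),
            "diagonal_strong": diag.count("strong"),
            "diagonal_total": len(diag),
        }
    else:
        log.warning("submap skipped: fewer than two datasets")
        report["stages"]["submap"] = {"skipped": "fewer than two datasets"}

    # --- stage 6: pathway activation scoring --------------------------------
    if syn is not None:
        pw_cfg = config.get("pathways") or {}
        profiles = {}
        for k, p in enumerate(PATHWAYS):
            train_pw, y = generate_pathway_training(
                syn, p, n_per_arm=int(pw_cfg.get("n_per_arm", 35)),
                seed=seed + 100 + k,
            )
            _, _, prof = train_and_score(
                train_pw, y, train_ds,
                k_genes=int(pw_cfg.get("k_genes", 100)),
                n_factors=int(pw_cfg.get("n_factors", 1)),
                n_iter=int(pw_cfg.get("n_iter", 3000)),
                burn_in=int(pw_cfg.get("burn_in", 500)),
                seed=seed + 200 + k,
                adjust=pw_cfg.get("adjust", "combat"),
            )
            profiles[p] = prof.probability
        activation = pd.DataFrame(profiles)
        act_path = out / "activation.tsv"
        activation.to_csv(act_path, sep="\t")
        report["stages"]["pathway_activation"] = {
            "path": str(act_path),
            "mean_probability": activation.mean().to_dict(),
        }

        # --- stage 7: activation-pattern clusters vs chemoresistance --------
        k_clusters = int((config.get("clusters") or {}).get("k", 7))
        assign, _ = cluster_profiles(activation, k=k_clusters)
        truth0 = truths[0].samples
        cluster_tab = pd.DataFrame({"cluster": assign})
        assoc = {}
        all_active = activation.mean(axis=1).groupby(assign).mean().idxmax()
        for drug in syn.resistance:
            res = cluster_vs_resistance(
                assign, truth0[f"res_prob_{drug}"], [all_active], drug=drug
            )
            assoc[drug] = res
        clus_path = out / "clusters.tsv"
        cluster_tab.to_csv(clus_path, sep="\t")
        (out / "cluster_resistance.json").write_text(json.dumps(assoc, indent=1))
        report["stages"]["cluster_resistance"] = {
            "path": str(clus_path),
            "associations": {d: {"p": a["p"], "direction": a["direction"]} for d, a in assoc.items()},
        }

        # --- stage 8: gene-set functional class scoring ----------------------
        fcs_cfg = config.get("fcs") or {}
        gene_sets = make_gene_sets(syn, seed=seed + 300)
        ras_state = truth0[f"pathway_{LET7_PATHWAY}"].astype(int)
        fcs = fcs_enrichment(
            train_ds, ras_state, gene_sets,
            n_random=int(fcs_cfg.get("n_random", 10000)),
            seed=seed + 400,
        )
        fcs_path = out / "fcs.tsv"
        fcs.table.to_csv(fcs_path, sep="\t")
        report["stages"]["fcs"] = {
            "path": str(fcs_path),
            "let7_p_LS": float(fcs.table.loc["LET7_ANALOG", "p_LS"]),
        }
    else:
        report["stages"]["pathway_activation"] = {"skipped": "no synthetic truth available"}
        report["stages"]["cluster_resistance"] = {"skipped": "no synthetic truth available"}
        report["stages"]["fcs"] = {"skipped": "no synthetic truth available"}

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, default=str))
    return report
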