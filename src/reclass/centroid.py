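"""Two-step multi-class nearest-centroid subtype classifier.

The classifier is built in two stages because two of the six sarcoma
subtypes (MPNST and SYN) overlap heavily in expression and cannot be
separated in a single multi-class model.  Step 1 discriminates LEIO, LIPO,
FIBRO, RHAB and a merged MPNST+SYN "composite" class using genes selected
by a one-way ANOVA F-test at a stringent threshold (default p <= 4e-7);
step 2 splits composite-assigned samples into MPNST vs SYN with its own
(two-class) selection.  Prediction assigns each sample to the class whose
centroid (per-class mean over selected genes) is nearest, by default under
one minus the centered Pearson correlation.

Cross-validation is leave-one-out with full gene re-selection inside every
fold, and significance is assessed by a label-permutation test over the
whole cross-validated accuracy.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import COMPOSITE, SUBTYPES, UNKNOWN, ExpressionDataset

STEP1_CLASSES = ("FIBRO", "LEIO", "LIPO", "RHAB", COMPOSITE)
STEP2_CLASSES = ("MPNST", "SYN")


class ClassifierError(ValueError):
    pass


@dataclass
class TwoStepConfig:
    """Tunable knobs of the two-step classifier.

    ``step1_p`` is the published step-1 F-test cutoff; ``step2_p`` applies
    to the far smaller two-class step.  ``fallback_n_genes``, when set,
    substitutes the top-n genes by p-value whenever a selection comes up
    empty (needed for cross-validation on null data, where the strict
    threshold would select nothing).
    """

    step1_p: float = 4e-7
    step2_p: float = 1e-4
    metric: str = "centered_correlation"  # or "euclidean"
    fallback_n_genes: Optional[int] = None
    reselect_in_cv: bool = True


@dataclass
class GeneSelection:
    genes: list
    f_statistic: pd.Series
    p_value: pd.Series
    threshold: float
    excluded: list = field(default_factory=list)


@dataclass
class CentroidModel:
    classes: list
    genes: list
    centroids: pd.DataFrame  # genes x classes
    metric: str = "centered_correlation"


@dataclass
class TwoStepModel:
    step1: CentroidModel
    step2: CentroidModel
    config: TwoStepConfig

    @property
    def union_genes(self) -> list:
        seen = dict.fromkeys(self.step1.genes)
        seen.update(dict.fromkeys(self.step2.genes))
        return list(seen)

    @property
    def n_union_genes(self) -> int:
        return len(self.union_genes)


@dataclass
class PredictionResult:
    predicted: pd.Series
    distances_step1: pd.DataFrame
    distances_step2: Optional[pd.DataFrame]
    step_path: pd.Series  # "1" or "1->2"
    margin: pd.Series
    ties: pd.Series


@dataclass
class CVReport:
    confusion: pd.DataFrame  # true x predicted
    accuracy: float
    sensitivity: pd.Series
    specificity: pd.Series
    n: int
    permutation_p: Optional[float] = None


@dataclass
class PortReport:
    lost_step1: list
    lost_step2: list


# ---------------------------------------------------------------------------
# Gene selection
# ---------------------------------------------------------------------------

def _anova_f(X: np.ndarray, group_indices) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-gene one-way ANOVA over column groups.

    Returns (F, p).  Genes that are constant everywhere get F = nan.
    """
    K = len(group_indices)
    sizes = np.array([len(ix) for ix in group_indices])
    N = sizes.sum()
    means = np.stack([X[:, ix].mean(axis=1) for ix in group_indices], axis=1)
    grand = (means * sizes).sum(axis=1) / N
    ssb = (sizes * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros(X.shape[0])
    for k, ix in enumerate(group_indices):
        ssw += ((X[:, ix] - means[:, k][:, None]) ** 2).sum(axis=1)
    msb = ssb / (K - 1)
    msw = ssw / (N - K)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
        F = np.where((ssw == 0) & (ssb > 0), np.inf, F)
        F = np.where((ssw == 0) & (ssb == 0), np.nan, F)
    p = np.where(np.isnan(F), np.nan, stats.f.sf(F, K - 1, N - K))
    return F, p


def f_select(
    ds: ExpressionDataset,
    labels: Optional[pd.Series] = None,
    p_threshold: float = 4e-7,
) -> GeneSelection:
    """Select class-discriminating genes by one-way ANOVA F-test.

    UNKNOWN samples are excluded.  Selected genes are sorted by ascending
    p-value.  Genes constant across all samples (0/0 F) are excluded with
    a warning.
    """
    labels = ds.labels if labels is None else labels.reindex(ds.values.columns)
    known = labels != UNKNOWN
    lab = labels[known]
    classes = sorted(lab.unique())
    if len(classes) < 2:
        raise ClassifierError("need at least two classes for F-test selection")
    cols = {s: i for i, s in enumerate(ds.sample_ids)}
    group_indices = []
    for c in classes:
        ix = [cols[s] for s in lab.index[lab == c]]
        if len(ix) < 2:
            raise ClassifierError(f"class {c!r} has fewer than 2 samples")
        group_indices.append(np.array(ix))
    X = ds.values.to_numpy(dtype=float)
    F, p = _anova_f(X, group_indices)
    excluded = [ds.gene_ids[i] for i in np.flatnonzero(np.isnan(F))]
    if excluded:
        warnings.warn(f"{len(excluded)} constant genes excluded from F-test")
    fs = pd.Series(F, index=ds.values.index)
    ps = pd.Series(p, index=ds.values.index)
    ok = ps.notna() & (ps <= p_threshold)
    selected = ps[ok].sort_values(kind="stable").index.tolist()
    return GeneSelection(selected, fs, ps, p_threshold, excluded)


def _top_n_by_p(selection: GeneSelection, n: int) -> list:
    ps = selection.p_value.dropna().sort_values(kind="stable")
    return ps.index[:n].tolist()


# ---------------------------------------------------------------------------
# Centroids and prediction
# ---------------------------------------------------------------------------

def fit_centroids(
    ds: ExpressionDataset,
    genes,
    labels: Optional[pd.Series] = None,
    metric: str = "centered_correlation",
) -> CentroidModel:
    """Per-class mean expression over the selected genes."""
    labels = ds.labels if labels is None else labels.reindex(ds.values.columns)
    genes = list(genes)
    missing = [g for g in genes if g not in ds.values.index]
    if missing:
        raise ClassifierError(f"genes absent from dataset: {missing[:5]}")
    known = labels != UNKNOWN
    lab = labels[known]
    classes = sorted(lab.unique())
    sub = ds.values.loc[genes]
    cent = {}
    for c in classes:
        members = lab.index[lab == c]
        if len(members) == 0:
            raise ClassifierError(f"empty class {c!r}")
        cent[c] = sub[members].mean(axis=1)
    centroids = pd.DataFrame(cent)
    return CentroidModel(classes=classes, genes=genes, centroids=centroids, metric=metric)


def _distances(model: CentroidModel, values: pd.DataFrame) -> pd.DataFrame:
    """Samples x classes distance matrix over the model genes."""
    X = values.loc[model.genes].to_numpy(dtype=float)  # genes x samples
    C = model.centroids.to_numpy(dtype=float)          # genes x classes
    if model.metric == "euclidean":
        d2 = (
            (X**2).sum(axis=0)[:, None]
            - 2 * X.T @ C
            + (C**2).sum(axis=0)[None, :]
        )
        D = np.sqrt(np.maximum(d2, 0.0))
    elif model.metric == "centered_correlation":
        Xc = X - X.mean(axis=0)
        Cc = C - C.mean(axis=0)
        xn = np.sqrt((Xc**2).sum(axis=0))
        cn = np.sqrt((Cc**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = (Xc.T @ Cc) / np.outer(xn, cn)
        corr = np.nan_to_num(corr, nan=0.0)  # constant vectors: treat as uncorrelated
        D = 1.0 - corr
    else:
        raise ClassifierError(f"unknown metric {model.metric!r}")
    return pd.DataFrame(D, index=values.columns, columns=model.classes)


def predict(model: CentroidModel, ds: ExpressionDataset) -> PredictionResult:
    """Nearest-centroid assignment with alphabetical tie-breaking.

    Exact distance ties are broken alphabetically (class order) and
    flagged.  Requires at least 3 model genes present in the dataset.
    """
    shared = [g for g in model.genes if g in ds.values.index]
    if len(shared) < 3:
        raise ClassifierError("fewer than 3 model genes present in dataset")
    sub = CentroidModel(
        model.classes, shared, model.centroids.loc[shared], model.metric
    )
    D = _distances(sub, ds.values)
    arr = D.to_numpy()
    best = arr.argmin(axis=1)  # argmin returns first (alphabetical) on ties
    predicted = pd.Series([model.classes[i] for i in best], index=D.index)
    sorted_d = np.sort(arr, axis=1)
    margin = pd.Series(sorted_d[:, 1] - sorted_d[:, 0], index=D.index)
    ties = pd.Series((arr == arr.min(axis=1, keepdims=True)).sum(axis=1) > 1, index=D.index)
    return PredictionResult(
        predicted=predicted,
        distances_step1=D,
        distances_step2=None,
        step_path=pd.Series("1", index=D.index),
        margin=margin,
        ties=ties,
    )


# ---------------------------------------------------------------------------
# Two-step model
# ---------------------------------------------------------------------------

def _composite_labels(labels: pd.Series) -> pd.Series:
    out = labels.copy()
    out[out.isin(STEP2_CLASSES)] = COMPOSITE
    return out


def fit_two_step(ds: ExpressionDataset, config: Optional[TwoStepConfig] = None) -> TwoStepModel:
    """Fit the full two-step classifier on a labeled training dataset.

    Requires all six subtype classes.  If the step-2 selection is empty at
    the configured threshold and no fallback is configured, an error
    advises changing ``step2_p``.
    """
    config = config or TwoStepConfig()
    labels = ds.labels
    present = set(labels.unique()) - {UNKNOWN}
    missing = set(SUBTYPES) - present
    if missing:
        raise ClassifierError(f"training labels missing classes: {sorted(missing)}")

    min_genes = 3  # correlation distance needs >= 3 genes
    lab1 = _composite_labels(labels)
    sel1 = f_select(ds, lab1, config.step1_p)
    genes1 = sel1.genes
    if len(genes1) < min_genes:
        if config.fallback_n_genes is None:
            raise ClassifierError(
                f"step-1 selection has {len(genes1)} genes (<{min_genes}); "
                "raise step1_p or set fallback_n_genes"
            )
        genes1 = _top_n_by_p(sel1, max(config.fallback_n_genes, min_genes))
    step1 = fit_centroids(ds, genes1, lab1, config.metric)

    pair = labels.index[labels.isin(STEP2_CLASSES)]
    ds2 = ds.subset_samples(pair)
    sel2 = f_select(ds2, labels.loc[pair], config.step2_p)
    genes2 = sel2.genes
    if len(genes2) < min_genes:
        if config.fallback_n_genes is None:
            raise ClassifierError(
                "step-2 selection too small at configured threshold; raise step2_p"
            )
        genes2 = _top_n_by_p(sel2, max(config.fallback_n_genes, min_genes))
    step2 = fit_centroids(ds2, genes2, labels.loc[pair], config.metric)
    return TwoStepModel(step1=step1, step2=step2, config=config)


def predict_two_step(model: TwoStepModel, ds: ExpressionDataset) -> PredictionResult:
    """Step-1 prediction, then step-2 re-prediction of composite calls."""
    res1 = predict(model.step1, ds)
    predicted = res1.predicted.copy()
    path = pd.Series("1", index=predicted.index)
    distances2 = None
    comp = predicted.index[predicted == COMPOSITE]
    if len(comp) > 0:
        res2 = predict(model.step2, ds.subset_samples(comp))
        predicted.loc[comp] = res2.predicted
        path.loc[comp] = "1->2"
        distances2 = res2.distances_step1
    return PredictionResult(
        predicted=predicted,
        distances_step1=res1.distances_step1,
        distances_step2=distances2,
        step_path=path,
        margin=res1.margin,
        ties=res1.ties,
    )


# ---------------------------------------------------------------------------
# Cross-validation and permutation significance
# ---------------------------------------------------------------------------

def _cv_report(true: pd.Series, pred: pd.Series) -> CVReport:
    classes = sorted(set(true.unique()) | set(pred.unique()))
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(true, pred):
        conf.loc[t, p] += 1
    n = int(conf.to_numpy().sum())
    acc = float(np.trace(conf.to_numpy())) / n
    sens, spec = {}, {}
    for c in classes:
        tp = conf.loc[c, c]
        fn = conf.loc[c].sum() - tp
        fp = conf[c].sum() - tp
        tn = n - tp - fn - fp
        sens[c] = tp / (tp + fn) if (tp + fn) else np.nan
        spec[c] = tn / (tn + fp) if (tn + fp) else np.nan
    return CVReport(conf, acc, pd.Series(sens), pd.Series(spec), n)


def _select_fold(X, cols, lab, threshold, fallback_n, min_genes=3):
    """Gene indices selected by F-test on the given columns (numpy path)."""
    classes = sorted(set(lab))
    groups = [np.array([c for c, l in zip(cols, lab) if l == k]) for k in classes]
    F, p = _anova_f(X, groups)
    p = np.where(np.isnan(p), np.inf, p)
    sel = np.flatnonzero(p <= threshold)
    if len(sel) < min_genes:
        if fallback_n is None:
            raise ClassifierError(
                "selection too small inside a cross-validation fold; "
                "set fallback_n_genes"
            )
        n = max(fallback_n, min_genes)
        sel = np.argpartition(p, n - 1)[:n]
    return sel, classes, groups


def _nearest_class(X, sel, groups, classes, test_col, metric):
    """Nearest-centroid call for one held-out column (numpy path)."""
    cent = np.stack([X[np.ix_(sel, g)].mean(axis=1) for g in groups], axis=1)
    x = X[sel, test_col]
    if metric == "euclidean":
        d = np.sqrt(((cent - x[:, None]) ** 2).sum(axis=0))
    else:
        xc = x - x.mean()
        cc = cent - cent.mean(axis=0)
        denom = np.sqrt((xc**2).sum()) * np.sqrt((cc**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = (cc.T @ xc) / denom
        d = 1.0 - np.nan_to_num(corr, nan=0.0)
    return classes[int(d.argmin())]


def loocv(
    ds: ExpressionDataset,
    config: Optional[TwoStepConfig] = None,
    labels: Optional[pd.Series] = None,
) -> CVReport:
    """Leave-one-out cross-validation of the two-step classifier.

    By default gene selection is redone inside every fold so the held-out
    sample never influences the genes used to predict it.  With
    ``config.reselect_in_cv`` False the (optimistic) fixed gene list from
    the full data is reused and only centroids are refit per fold.
    """
    config = config or TwoStepConfig()
    lab_series = ds.labels if labels is None else labels.reindex(ds.values.columns)
    known_mask = (lab_series != UNKNOWN).to_numpy()
    known_idx = np.flatnonzero(known_mask)
    lab_known = lab_series.to_numpy()[known_idx]
    for c, cnt in zip(*np.unique(lab_known, return_counts=True)):
        if cnt < 2:
            raise ClassifierError(f"class {c!r} has fewer than 2 samples")
    X = ds.values.to_numpy(dtype=float)
    gene_ids = ds.gene_ids
    lab1_known = np.where(np.isin(lab_known, STEP2_CLASSES), COMPOSITE, lab_known)
    pair_pos = np.flatnonzero(np.isin(lab_known, STEP2_CLASSES))

    fixed1 = fixed2 = None
    if not config.reselect_in_cv:
        full = fit_two_step(
            ds.subset_samples([ds.sample_ids[i] for i in known_idx])
            if labels is None else
            ExpressionDataset(
                ds.values.iloc[:, known_idx],
                lab_series.iloc[known_idx],
                ds.batch.iloc[known_idx],
                ds.log_scale,
            ),
            config,
        )
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        fixed1 = np.array([gene_pos[g] for g in full.step1.genes])
        fixed2 = np.array([gene_pos[g] for g in full.step2.genes])

    preds = []
    for j, i in enumerate(known_idx):
        train_pos = np.delete(np.arange(len(known_idx)), j)
        cols = known_idx[train_pos]
        lab1 = lab1_known[train_pos]
        if fixed1 is None:
            sel1, classes1, groups1 = _select_fold(
                X, cols, lab1, config.step1_p, config.fallback_n_genes
            )
        else:
            sel1 = fixed1
            classes1 = sorted(set(lab1))
            groups1 = [cols[lab1 == k] for k in classes1]
        call = _nearest_class(X, sel1, groups1, classes1, i, config.metric)
        if call == COMPOSITE:
            pair_train = pair_pos[pair_pos != j]
            cols2 = known_idx[pair_train]
            lab2 = lab_known[pair_train]
            if fixed2 is None:
                sel2, classes2, groups2 = _select_fold(
                    X, cols2, lab2, config.step2_p, config.fallback_n_genes
                )
            else:
                sel2 = fixed2
                classes2 = sorted(set(lab2))
                groups2 = [cols2[lab2 == k] for k in classes2]
            call = _nearest_class(X, sel2, groups2, classes2, i, config.metric)
        preds.append(call)

    sample_ids = [ds.sample_ids[i] for i in known_idx]
    true = pd.Series(lab_known, index=sample_ids)
    pred = pd.Series(preds, index=sample_ids)
    return _cv_report(true, pred)


def permutation_test(
    ds: ExpressionDataset,
    config: Optional[TwoStepConfig] = None,
    n_perm: int = 100,
    seed: int = 0,
    observed_accuracy: Optional[float] = None,
) -> float:
    """Label-permutation significance of the cross-validated accuracy.

    p = (1 + #{permuted accuracy >= observed}) / (n_perm + 1).

    Under permuted labels the strict selection thresholds typically pass
    nothing, which would leave the null statistic undefined; permutation
    replicates therefore always fall back to the top genes by p-value
    (``fallback_n_genes``, default 10) when a selection comes up short.
    The observed accuracy uses the caller's configuration unchanged.
    """
    if n_perm < 19:
        raise ClassifierError("n_perm must be at least 19")
    config = config or TwoStepConfig()
    if observed_accuracy is None:
        observed_accuracy = loocv(ds, config).accuracy
    perm_config = config
    if config.fallback_n_genes is None:
        perm_config = dataclasses.replace(config, fallback_n_genes=10)
    rng = np.random.default_rng(seed)
    known = ds.labels.index[ds.labels != UNKNOWN]
    base = ds.labels.loc[known].to_numpy()
    count = 0
    for _ in range(n_perm):
        permuted = ds.labels.copy()
        permuted.loc[known] = rng.permutation(base)
        acc = loocv(ds, perm_config, labels=permuted).accuracy
        if acc >= observed_accuracy:
            count += 1
    return (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def two_step_to_dict(model: TwoStepModel) -> dict:
    """JSON-ready representation (classes, genes, centroids, metric, thresholds)."""

    def centroid_dict(m: CentroidModel) -> dict:
        return {
            "classes": m.classes,
            "genes": m.genes,
            "metric": m.metric,
            "centroids": {c: m.centroids[c].tolist() for c in m.classes},
        }

    return {
        "step1": centroid_dict(model.step1),
        "step2": centroid_dict(model.step2),
        "config": {
            "step1_p": model.config.step1_p,
            "step2_p": model.config.step2_p,
            "metric": model.config.metric,
        },
        "n_union_genes": model.n_union_genes,
    }


def two_step_from_dict(d: dict) -> TwoStepModel:
    def centroid_model(cd: dict) -> CentroidModel:
        centroids = pd.DataFrame(
            {c: cd["centroids"][c] for c in cd["classes"]}, index=cd["genes"]
        )
        return CentroidModel(cd["classes"], cd["genes"], centroids, cd["metric"])

    cfg = TwoStepConfig(
        step1_p=d["config"]["step1_p"],
        step2_p=d["config"]["step2_p"],
        metric=d["config"]["metric"],
    )
    return TwoStepModel(centroid_model(d["step1"]), centroid_model(d["step2"]), cfg)


# ---------------------------------------------------------------------------
# Cross-platform porting
# ---------------------------------------------------------------------------

def port_model(
    model: TwoStepModel,
    target_ds: ExpressionDataset,
    config: Optional[TwoStepConfig] = None,
) -> tuple[TwoStepModel, PortReport]:
    """Refit the model's centroids on another platform's training data.

    Keeps the intersection of model genes with the target gene set (losses
    are reported), then refits centroids on the target's labeled samples
    without re-selecting genes — the "modified predictor" used when moving
    between platforms with partial gene-content overlap.
    """
    config = config or model.config
    target_genes = set(target_ds.gene_ids)
    keep1 = [g for g in model.step1.genes if g in target_genes]
    keep2 = [g for g in model.step2.genes if g in target_genes]
    lost1 = [g for g in model.step1.genes if g not in target_genes]
    lost2 = [g for g in model.step2.genes if g not in target_genes]
    if len(keep1) < 10:
        raise ClassifierError(
            f"only {len(keep1)} step-1 genes survive on target platform (<10)"
        )
    lab1 = _composite_labels(target_ds.labels)
    step1 = fit_centroids(target_ds, keep1, lab1, config.metric)
    pair = target_ds.labels.index[target_ds.labels.isin(STEP2_CLASSES)]
    step2 = fit_centroids(
        target_ds.subset_samples(pair), keep2, target_ds.labels.loc[pair], config.metric
    )
    return TwoStepModel(step1, step2, config), PortReport(lost1, lost2)
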