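"""Expression dataset container and I/O.

The analyses in this package operate on log2-scale gene-by-sample
expression matrices with per-sample class labels (one of the six sarcoma
subtypes, or ``UNKNOWN`` for histologically unclassifiable tumors) and a
dataset/platform ("batch") tag per sample.  All on-disk formats are plain
tab-delimited text.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Conventional sarcoma subtype labels handled by the classifier.
SUBTYPES = ("FIBRO", "LEIO", "LIPO", "MPNST", "RHAB", "SYN")
#: Merged MPNST+SYN class used in classifier step 1.
COMPOSITE = "COMPOSITE"
#: Label for histologically unclassifiable samples (MFH/NOS analogues).
UNKNOWN = "UNKNOWN"

VALID_LABELS = frozenset(SUBTYPES) | {COMPOSITE, UNKNOWN}


class DatasetError(ValueError):
    """Raised for malformed or inconsistent expression datasets."""


@dataclass
class ExpressionDataset:
    """A log-scale genes x samples expression matrix with sample annotation.

    Parameters
    ----------
    values
        DataFrame of expression values, genes in rows (index = gene ids),
        samples in columns.  NaN marks missing measurements.
    labels
        Per-sample class label, indexed by sample id.  Anything outside the
        recognized subtype vocabulary is stored as ``UNKNOWN``.
    batch
        Per-sample dataset/platform tag, indexed by sample id.
    log_scale
        Whether values are on log2 scale.  Normalization requires it.
    """

    values: pd.DataFrame
    labels: pd.Series
    batch: pd.Series
    log_scale: bool = True

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise DatasetError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = sorted(set(self.values.columns[self.values.columns.duplicated()]))
            raise DatasetError(f"duplicate sample ids: {dups}")
        self.labels = self.labels.reindex(self.values.columns)
        self.batch = self.batch.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise DatasetError(f"samples missing from annotation: {missing}")
        norm = self.labels.astype(str).str.upper()
        self.labels = norm.where(norm.isin(VALID_LABELS), UNKNOWN)

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def labeled_mask(self) -> np.ndarray:
        """Boolean array marking samples with a conventional class label."""
        return (self.labels != UNKNOWN).to_numpy()

    def subset_genes(self, genes) -> "ExpressionDataset":
        return replace(self, values=self.values.loc[list(genes)])

    def subset_samples(self, samples) -> "ExpressionDataset":
        samples = list(samples)
        return ExpressionDataset(
            values=self.values[samples],
            labels=self.labels.loc[samples],
            batch=self.batch.loc[samples],
            log_scale=self.log_scale,
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.copy(), self.labels.copy(), self.batch.copy(), self.log_scale
        )


@dataclass
class PlatformMap:
    """Probe-to-gene-symbol mapping; many probes may share one symbol."""

    mapping: dict  # source_id -> symbol

    def __post_init__(self) -> None:
        if not isinstance(self.mapping, dict):
            self.mapping = dict(self.mapping)


@dataclass
class MappingReport:
    n_input: int
    n_unmapped: int
    n_collapsed_groups: int
    n_output: int
    unmapped: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_table(path, annotation_path, log_scale: bool = True) -> ExpressionDataset:
    """Read a tab-delimited expression matrix plus its sample annotation.

    The matrix file has a header row of sample ids and gene ids in the first
    column; the annotation file has columns ``sample_id``, ``label`` and
    ``batch`` (one row per sample, any order).
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    required = {"sample_id", "label", "batch"}
    if not required.issubset(ann.columns):
        raise DatasetError(f"annotation must have columns {sorted(required)}")
    if ann["sample_id"].duplicated().any():
        dups = sorted(set(ann.loc[ann["sample_id"].duplicated(), "sample_id"]))
        raise DatasetError(f"duplicate sample ids in annotation: {dups}")
    ann = ann.set_index("sample_id")
    absent = [s for s in values.columns if s not in ann.index]
    if absent:
        raise DatasetError(f"samples missing from annotation: {absent}")
    ann = ann.reindex(values.columns)
    labels = ann["label"].fillna(UNKNOWN)
    return ExpressionDataset(values, labels, ann["batch"], log_scale=log_scale)


def write_expression_table(ds: ExpressionDataset, path, annotation_path=None) -> None:
    out = ds.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    if annotation_path is not None:
        ann = pd.DataFrame(
            {"sample_id": ds.sample_ids, "label": ds.labels.values, "batch": ds.batch.values}
        )
        ann.to_csv(annotation_path, sep="\t", index=False)


def read_platform_map(path) -> PlatformMap:
    """Read a two-column (source_id, symbol) tab-delimited mapping table."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if not {"source_id", "symbol"}.issubset(tab.columns):
        raise DatasetError("platform map must have columns source_id, symbol")
    grouped = tab.groupby("source_id")["symbol"].nunique()
    conflicted = list(grouped.index[grouped > 1])
    if conflicted:
        raise DatasetError(f"source ids mapped to multiple symbols: {conflicted}")
    return PlatformMap(dict(zip(tab["source_id"], tab["symbol"])))


# ---------------------------------------------------------------------------
# Normalization / cleaning
# ---------------------------------------------------------------------------

def median_center_samples(ds: ExpressionDataset) -> ExpressionDataset:
    """Median normalization: subtract each sample's median over non-missing genes.

    After centering every sample column has median exactly zero; the
    missingness pattern is preserved.  Idempotent.
    """
    if not ds.log_scale:
        raise DatasetError("median centering expects log-scale values")
    vals = ds.values.to_numpy(dtype=float)
    all_missing = np.all(np.isnan(vals), axis=0)
    if all_missing.any():
        bad = [ds.sample_ids[i] for i in np.flatnonzero(all_missing)]
        raise DatasetError(f"samples with no non-missing values: {bad}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(vals, axis=0)
    centered = pd.DataFrame(vals - med, index=ds.values.index, columns=ds.values.columns)
    return replace(ds, values=centered)


def impute_missing(ds: ExpressionDataset, max_missing_fraction: float = 0.5):
    """Impute missing cells with the per-gene median over non-missing samples.

    Genes missing in more than ``max_missing_fraction`` of samples are
    dropped.  Returns ``(dataset, dropped_gene_ids)``.
    """
    vals = ds.values.to_numpy(dtype=float)
    missing = np.isnan(vals)
    frac = missing.mean(axis=1)
    drop = frac > max_missing_fraction
    dropped = [ds.gene_ids[i] for i in np.flatnonzero(drop)]
    keep = ~drop
    vals = vals[keep]
    missing = missing[keep]
    if missing.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(vals, axis=1)
        fill = np.broadcast_to(med[:, None], vals.shape)
        vals = np.where(missing, fill, vals)
    values = pd.DataFrame(
        vals, index=ds.values.index[keep], columns=ds.values.columns
    )
    return replace(ds, values=values), dropped


def map_to_symbols(ds: ExpressionDataset, platform_map: PlatformMap):
    """Collapse probe-level rows to gene symbols by averaging log values.

    Rows without a mapping are dropped; rows sharing a symbol are averaged
    per sample.  Returns ``(dataset, MappingReport)`` so cross-platform
    predictor-gene losses can be audited.
    """
    if not platform_map.mapping:
        raise DatasetError("empty platform map")
    mapping = platform_map.mapping
    symbols = ds.values.index.map(lambda g: mapping.get(g))
    mapped = symbols.notna()
    unmapped_ids = list(ds.values.index[~mapped])
    sub = ds.values[mapped]
    sym = pd.Index(symbols[mapped], name="gene_id")
    collapsed = sub.groupby(sym, sort=False).mean()
    n_groups = int((sub.groupby(sym, sort=False).size() > 1).sum())
    report = MappingReport(
        n_input=ds.n_genes,
        n_unmapped=len(unmapped_ids),
        n_collapsed_groups=n_groups,
        n_output=collapsed.shape[0],
        unmapped=unmapped_ids,
    )
    return replace(ds, values=collapsed), report


def variance_filter(ds: ExpressionDataset, fraction: float = 1 / 3) -> ExpressionDataset:
    """Keep the top ``ceil(fraction * n_genes)`` genes by sample variance.

    The default fraction of one third matches the genome-wide clustering
    convention used for the molecular-match analysis.  Ties are broken by
    input order and the original row order is preserved.
    """
    if not (0 < fraction <= 1):
        raise DatasetError("fraction must be in (0, 1]")
    vals = ds.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise DatasetError("variance filter requires imputed (complete) data")
    n_keep = math.ceil(fraction * ds.n_genes)
    var = vals.var(axis=1, ddof=1) if ds.n_samples > 1 else np.zeros(ds.n_genes)
    order = np.argsort(-var, kind="stable")[:n_keep]
    keep_mask = np.zeros(ds.n_genes, dtype=bool)
    keep_mask[order] = True
    return replace(ds, values=ds.values[keep_mask])


def merge_datasets(ds_list) -> ExpressionDataset:
    """Collate several datasets on their common genes.

    Gene set is the intersection of all inputs in the first dataset's row
    order; sample columns are concatenated with labels and batch tags
    preserved.  Sample ids must be pairwise disjoint.
    """
    ds_list = list(ds_list)
    if len(ds_list) < 2:
        raise DatasetError("merge requires at least two datasets")
    genes = list(ds_list[0].gene_ids)
    for ds in ds_list[1:]:
        present = set(ds.gene_ids)
        genes = [g for g in genes if g in present]
    if not genes:
        raise DatasetError("empty gene intersection")
    seen = set()
    for ds in ds_list:
        overlap = seen.intersection(ds.sample_ids)
        if overlap:
            raise DatasetError(f"shared sample ids across datasets: {sorted(overlap)}")
        seen.update(ds.sample_ids)
    values = pd.concat([ds.values.loc[genes] for ds in ds_list], axis=1)
    labels = pd.concat([ds.labels for ds in ds_list])
    batch = pd.concat([ds.batch for ds in ds_list])
    return ExpressionDataset(values, labels, batch, log_scale=ds_list[0].log_scale)
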