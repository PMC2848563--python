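"""Synthetic multi-dataset sarcoma expression cohorts with known truth.

The generator emulates the statistical structure the analysis pipeline
assumes: six latent subtypes with disjoint marker-gene blocks, a pair of
subtypes (the MPNST/SYN analogues) sharing an additional overlapping
block so that a single-step six-class model is ill-posed, per-dataset
additive/multiplicative batch effects, unlabeled "dedifferentiated"
samples whose subtype-specific shifts are attenuated by a scalar factor
(the MFH/NOS analogue), three latent binary pathway-activation states
each driving a dedicated gene block, a pathway-responsive gene block
that is down-shifted when the second pathway is active (the let-7-target
analogue), and per-drug chemoresistance probabilities probit-linked to
the pathway states.

Class sizes default to the proportions of the largest real cohort this
kind of study draws on (SYN 16, LEIO 17, LIPO 33, MPNST 6, FIBRO 7,
RHAB 6).  The marker effect size (3.5 log2 units over unit noise) was set
by an a-priori power calculation so that block genes are detectable at
the classifier's stringent F-test threshold given these small classes;
see the methods documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import UNKNOWN, ExpressionDataset
from .genesets import write_gmt

PATHWAYS = ("SRC", "RAS", "PI3K")
#: Pathway whose activation suppresses the miRNA-target analogue block.
LET7_PATHWAY = "RAS"


class SimulationError(ValueError):
    pass


def _default_class_sizes():
    return {"SYN": 16, "LEIO": 17, "LIPO": 33, "MPNST": 6, "FIBRO": 7, "RHAB": 6}


def _default_resistance():
    # drug -> (probit intercept, weights over (SRC, RAS, PI3K) states)
    return {
        "adriamycin": (-2.0, (1.0, 1.0, 1.0)),
        "cyclophosphamide": (-1.0, (2.0, 0.0, 0.0)),
        "docetaxel": (-1.0, (0.0, 2.0, 0.0)),
    }


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    class_sizes: dict = field(default_factory=_default_class_sizes)
    marker_block_size: int = 40
    marker_effect: float = 3.5       # log2 units; see module docstring
    composite_block_size: int = 40
    noise_sd: float = 1.0
    batch_additive_sd: float = 0.5
    batch_scale_log_sd: float = 0.25
    n_unknown: int = 30
    attenuation: float = 0.5
    pathway_block_size: int = 30
    pathway_effect: float = 1.5      # shift per pathway-block gene when active
    pathway_prob: float = 0.5
    resistance: dict = field(default_factory=_default_resistance)
    let7_set_size: int = 50
    let7_effect: float = 1.0
    n_null_sets: int = 20
    null_set_size: int = 50
    seed: int = 0


@dataclass
class SyntheticTruth:
    samples: pd.DataFrame     # per-sample truth (class, attenuation, states, resistance)
    blocks: dict              # block name -> list of gene ids


def gene_blocks(config: SyntheticConfig) -> dict:
    """Deterministic disjoint block layout over gene ids G0000..G{n-1}."""
    classes = sorted(config.class_sizes)
    need = (
        len(classes) * config.marker_block_size
        + config.composite_block_size
        + len(PATHWAYS) * config.pathway_block_size
        + config.let7_set_size
    )
    if need > config.n_genes:
        raise SimulationError(
            f"block layout needs {need} genes but n_genes={config.n_genes}"
        )
    width = max(4, len(str(config.n_genes - 1)))
    ids = [f"G{i:0{width}d}" for i in range(config.n_genes)]
    blocks = {}
    cursor = 0
    for c in classes:
        blocks[f"marker_{c}"] = ids[cursor : cursor + config.marker_block_size]
        cursor += config.marker_block_size
    blocks["composite"] = ids[cursor : cursor + config.composite_block_size]
    cursor += config.composite_block_size
    for p in PATHWAYS:
        blocks[f"pathway_{p}"] = ids[cursor : cursor + config.pathway_block_size]
        cursor += config.pathway_block_size
    blocks["let7_targets"] = ids[cursor : cursor + config.let7_set_size]
    cursor += config.let7_set_size
    blocks["_null"] = ids[cursor:]
    blocks["_all_ids"] = ids
    return blocks


def _signal_matrix(config, blocks, classes_per_sample, attenuations, pathway_states):
    """Noise-free expected expression, genes x samples."""
    ids = blocks["_all_ids"]
    index = {g: i for i, g in enumerate(ids)}
    n = len(classes_per_sample)
    M = np.zeros((config.n_genes, n))
    for j, (c, a) in enumerate(zip(classes_per_sample, attenuations)):
        rows = [index[g] for g in blocks[f"marker_{c}"]]
        M[rows, j] += config.marker_effect * a
        if c in ("MPNST", "SYN"):
            rows = [index[g] for g in blocks["composite"]]
            M[rows, j] += config.marker_effect * a
        for k, p in enumerate(PATHWAYS):
            if pathway_states[j, k]:
                rows = [index[g] for g in blocks[f"pathway_{p}"]]
                M[rows, j] += config.pathway_effect
                if p == LET7_PATHWAY:
                    rows = [index[g] for g in blocks["let7_targets"]]
                    M[rows, j] -= config.let7_effect
    return M


def _resistance_truth(config, pathway_states):
    cols = {}
    for drug, (alpha, w) in config.resistance.items():
        lin = alpha + pathway_states @ np.asarray(w, dtype=float)
        cols[f"res_prob_{drug}"] = stats.norm.cdf(lin)
    return cols


def generate_cohort(
    config: SyntheticConfig | None = None,
    seed: int | None = None,
    batch_name: str = "D1",
    batch_effects: bool = False,
    sample_prefix: str = "",
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """One dataset: labeled samples per class plus attenuated UNKNOWN samples.

    Labeled samples carry their subtype shifts at full strength; the
    ``n_unknown`` extra samples draw a latent subtype from the class-size
    proportions but have their subtype shifts multiplied by
    ``config.attenuation`` and are labeled UNKNOWN.  Fully reproducible
    from the seed.
    """
    config = config or SyntheticConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    blocks = gene_blocks(config)
    classes = sorted(config.class_sizes)

    true_class = []
    attenuation = []
    labels = []
    for c in classes:
        true_class += [c] * config.class_sizes[c]
        attenuation += [1.0] * config.class_sizes[c]
        labels += [c] * config.class_sizes[c]
    sizes = np.array([config.class_sizes[c] for c in classes], dtype=float)
    probs = sizes / sizes.sum()
    latent = rng.choice(classes, size=config.n_unknown, p=probs)
    true_class += list(latent)
    attenuation += [config.attenuation] * config.n_unknown
    labels += [UNKNOWN] * config.n_unknown

    n = len(true_class)
    sample_ids = [f"{sample_prefix}{batch_name}_S{j:03d}" for j in range(n)]
    pathway_states = rng.random((n, len(PATHWAYS))) < config.pathway_prob

    M = _signal_matrix(config, blocks, true_class, attenuation, pathway_states)
    noise = rng.normal(0.0, config.noise_sd, size=M.shape)
    if batch_effects:
        gamma = rng.normal(0.0, config.batch_additive_sd, size=config.n_genes)
        delta = np.exp(rng.normal(0.0, config.batch_scale_log_sd, size=config.n_genes))
        X = M + gamma[:, None] + delta[:, None] * noise
    else:
        X = M + noise

    values = pd.DataFrame(X, index=blocks["_all_ids"], columns=sample_ids)
    ds = ExpressionDataset(
        values=values,
        labels=pd.Series(labels, index=sample_ids),
        batch=pd.Series(batch_name, index=sample_ids),
    )
    truth_cols = {
        "true_class": true_class,
        "attenuation": attenuation,
        "label": labels,
    }
    for k, p in enumerate(PATHWAYS):
        truth_cols[f"pathway_{p}"] = pathway_states[:, k]
    truth_cols.update(_resistance_truth(config, pathway_states))
    truth = pd.DataFrame(truth_cols, index=sample_ids)
    for drug in config.resistance:
        truth[f"resistant_{drug}"] = (
            rng.random(n) < truth[f"res_prob_{drug}"].to_numpy()
        )
    block_export = {k: v for k, v in blocks.items() if not k.startswith("_")}
    return ds, SyntheticTruth(samples=truth, blocks=block_export)


def generate_multi_dataset(
    config: SyntheticConfig | None = None,
    n_datasets: int = 2,
    seed: int | None = None,
    gene_keep_fraction: float = 0.9,
) -> list:
    """Independent datasets sharing class and block definitions.

    Each dataset gets its own samples, noise, and per-gene batch effects;
    optionally only a random subset of genes is retained per dataset to
    emulate platform gene-content mismatch.
    """
    config = config or SyntheticConfig()
    if n_datasets < 2:
        raise SimulationError("n_datasets must be >= 2")
    seed = config.seed if seed is None else seed
    master = np.random.default_rng(seed)
    out = []
    for d in range(n_datasets):
        sub_seed = int(master.integers(0, 2**31 - 1))
        ds, truth = generate_cohort(
            config, seed=sub_seed, batch_name=f"D{d+1}", batch_effects=True
        )
        if gene_keep_fraction < 1.0:
            keep_rng = np.random.default_rng(sub_seed + 1)
            n_keep = int(round(gene_keep_fraction * config.n_genes))
            keep = np.sort(keep_rng.choice(config.n_genes, size=n_keep, replace=False))
            ds = replace(ds, values=ds.values.iloc[keep])
        out.append((ds, truth))
    return out


def generate_pathway_training(
    config: SyntheticConfig | None = None,
    pathway_id: str = "SRC",
    n_per_arm: int = 35,
    seed: int = 0,
) -> tuple[ExpressionDataset, pd.Series]:
    """Two-class in-vitro analogue: pathway experimentally ON vs control.

    The ON arm carries the pathway block shifted by the same
    ``pathway_effect`` the tumors experience (and, for the let-7-linked
    pathway, the responsive block down-shifted).  The arrays carry their
    own batch tag and additive offset so that cross-platform adjustment
    during scoring is exercised.
    """
    config = config or SyntheticConfig()
    if pathway_id not in PATHWAYS:
        raise SimulationError(f"unknown pathway {pathway_id!r}")
    rng = np.random.default_rng(seed)
    blocks = gene_blocks(config)
    index = {g: i for i, g in enumerate(blocks["_all_ids"])}
    n = 2 * n_per_arm
    y = np.array([0] * n_per_arm + [1] * n_per_arm)
    M = np.zeros((config.n_genes, n))
    rows = [index[g] for g in blocks[f"pathway_{pathway_id}"]]
    M[np.ix_(rows, np.flatnonzero(y == 1))] += config.pathway_effect
    if pathway_id == LET7_PATHWAY:
        rows = [index[g] for g in blocks["let7_targets"]]
        M[np.ix_(rows, np.flatnonzero(y == 1))] -= config.let7_effect
    gamma = rng.normal(0.0, config.batch_additive_sd, size=config.n_genes)
    X = M + gamma[:, None] + rng.normal(0.0, config.noise_sd, size=M.shape)
    batch = f"INVITRO_{pathway_id}"
    sample_ids = [f"{batch}_S{j:02d}" for j in range(n)]
    values = pd.DataFrame(X, index=blocks["_all_ids"], columns=sample_ids)
    ds = ExpressionDataset(
        values=values,
        labels=pd.Series(UNKNOWN, index=sample_ids),
        batch=pd.Series(batch, index=sample_ids),
    )
    return ds, pd.Series(y, index=sample_ids)


def make_gene_sets(config: SyntheticConfig | None = None, seed: int = 0) -> dict:
    """The enriched miRNA-target analogue set plus null sets.

    ``LET7_ANALOG`` is exactly the pathway-responsive block; null sets are
    drawn without replacement from genes outside every block.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    blocks = gene_blocks(config)
    null_pool = np.array(blocks["_null"])
    if len(null_pool) < config.null_set_size:
        raise SimulationError("not enough non-block genes for null sets")
    sets = {"LET7_ANALOG": list(blocks["let7_targets"])}
    for i in range(config.n_null_sets):
        pick = rng.choice(null_pool, size=config.null_set_size, replace=False)
        sets[f"NULL_{i+1:02d}"] = sorted(pick.tolist())
    return sets


def write_gene_sets(config: SyntheticConfig | None, path, seed: int = 0) -> dict:
    """Write the generated gene sets as GMT; returns the mapping written."""
    sets = make_gene_sets(config, seed)
    desc = {"LET7_ANALOG": "pathway-responsive miRNA-target analogue"}
    write_gmt(sets, path, descriptions=desc)
    return sets
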