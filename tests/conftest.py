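import numpy as np
import pandas as pd
import pytest

from reclass import ExpressionDataset, SyntheticConfig, generate_cohort


def make_dataset(values, labels=None, batch="B1", gene_prefix="G", sample_prefix="S"):
    """Small helper: build an ExpressionDataset from a plain array."""
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j}" for j in range(values.shape[1])]
    labels = labels if labels is not None else ["UNKNOWN"] * values.shape[1]
    return ExpressionDataset(
        values=pd.DataFrame(values, index=genes, columns=samples),
        labels=pd.Series(labels, index=samples),
        batch=pd.Series(batch, index=samples),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort used by the recovery checks (seed 7)."""
    return generate_cohort(SyntheticConfig(), seed=7)


@pytest.fixture(scope="session")
def null_config():
    """Scaled-down no-signal cohort configuration for null-calibration checks."""
    return SyntheticConfig(
        n_genes=300,
        marker_block_size=10,
        composite_block_size=10,
        pathway_block_size=10,
        let7_set_size=10,
        null_set_size=10,
        class_sizes={c: 6 for c in ("SYN", "LEIO", "LIPO", "MPNST", "FIBRO", "RHAB")},
        n_unknown=0,
        marker_effect=0.0,
    )
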