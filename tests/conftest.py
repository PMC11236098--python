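import numpy as np
import pandas as pd
import pytest

from scpruner import LabelVector, NormalizedMatrix
from scpruner import matrix as mx
from scpruner.ensemble import PathPredictionMatrix
from scpruner.simulate import SimulationConfig, simulate


def make_norm(values, gene_prefix="g"):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        values,
        [f"c{i}" for i in range(values.shape[0])],
        [f"{gene_prefix}{j}" for j in range(values.shape[1])],
        library_median=1.0,
    )


def random_preds(n_paths, n_cells, categories, seed, sharp=False):
    """A synthetic PathPredictionMatrix with consistent labels/probabilities."""
    rng = np.random.default_rng(seed)
    k = len(categories)
    probs = rng.dirichlet(np.ones(k) * (0.3 if sharp else 1.0),
                          size=(n_paths, n_cells))
    codes = probs.argmax(axis=2)
    labels = np.asarray(categories, dtype=object)[codes]
    return PathPredictionMatrix(labels, probs, list(categories))


@pytest.fixture(scope="session")
def tiny_fixture():
    """Small separable 3-type fixture shared by the slower integration tests."""
    cfg = SimulationConfig(
        n_cells_ref=180, n_cells_query=120, n_genes=90,
        cell_types=("alpha", "beta", "gamma"), markers_per_type=8,
        marker_fold_change=8.0, seed=7,
    )
    ref, ref_y, query, query_y = simulate(cfg)
    ref_norm = mx.normalize(mx.qc_filter(ref, 3, 10))
    y = mx.labels_for(ref_norm, pd.Series(ref_y.labels, index=ref.cell_ids))
    query_norm = mx.normalize(query)
    ref_norm, query_norm = mx.align_genes(ref_norm, query_norm)
    return cfg, ref_norm, y, query_norm, query_y
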