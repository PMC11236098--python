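"""Seeded negative-binomial scRNA-seq simulator with known marker structure.

Each cell type owns a disjoint block of marker genes whose mean expression
is elevated by a fold change over a shared baseline; counts are drawn from
a gamma-Poisson (negative binomial) model with per-cell log-normal library
scaling.  Cell types listed in ``novel_types`` appear only in the query, so
open-set rejection can be exercised with exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError
from .matrix import CountMatrix, LabelVector


@dataclass
class SimulationConfig:
    n_cells_ref: int = 2000
    n_cells_query: int = 1000
    n_genes: int = 1000
    cell_types: tuple[str, ...] = ("alpha", "beta", "gamma", "delta", "epsilon")
    proportions: tuple[float, ...] | None = None  # default: equal
    markers_per_type: int = 25
    marker_fold_change: float = 8.0
    nb_mean: float = 0.5
    nb_dispersion: float = 0.25
    libsize_sigma: float = 0.3
    novel_types: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.cell_types)
        if self.proportions is None:
            self.proportions = tuple(1.0 / k for _ in range(k))
        if len(self.proportions) != k:
            raise ConfigError("one proportion per cell type required")
        if abs(sum(self.proportions) - 1.0) > 1e-8:
            raise ConfigError("proportions must sum to 1")
        if self.markers_per_type * k > self.n_genes:
            raise ConfigError("marker blocks exceed the gene count")
        if self.marker_fold_change < 1.0:
            raise ConfigError("marker_fold_change must be >= 1")
        unknown = set(self.novel_types) - set(self.cell_types)
        if unknown:
            raise ConfigError(f"novel_types not among cell_types: {sorted(unknown)}")
        if len(self.novel_types) == len(self.cell_types):
            raise ConfigError("at least one cell type must remain in the reference")


def marker_genes(cfg: SimulationConfig) -> dict[str, np.ndarray]:
    """Ground-truth marker gene indices per cell type (disjoint blocks)."""
    out = {}
    for t, name in enumerate(cfg.cell_types):
        start = t * cfg.markers_per_type
        out[name] = np.arange(start, start + cfg.markers_per_type)
    return out


def _allocate(n: int, types: list[str], props: list[float],
              rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of n cells to types, then shuffled."""
    raw = np.asarray(props) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1
    assignment = np.repeat(np.arange(len(types)), counts)
    rng.shuffle(assignment)
    return assignment


def _draw_counts(cfg: SimulationConfig, type_idx: np.ndarray, mean_rows: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    n = len(type_idx)
    libfac = np.exp(rng.normal(0.0, cfg.libsize_sigma, size=n))
    mu = mean_rows[type_idx] * libfac[:, None]
    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape, mu * cfg.nb_dispersion)
    return rng.poisson(lam).astype(np.int64)


def simulate(cfg: SimulationConfig) -> tuple[CountMatrix, LabelVector,
                                             CountMatrix, LabelVector]:
    """Generate (reference counts, reference labels, query counts, query labels).

    The reference draws only from the non-novel cell types (proportions
    renormalized); the query draws from all types at the stated proportions.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"gene_{j:05d}" for j in range(cfg.n_genes)]
    types = list(cfg.cell_types)
    markers = marker_genes(cfg)
    mean_rows = np.full((len(types), cfg.n_genes), cfg.nb_mean)
    for t, name in enumerate(types):
        mean_rows[t, markers[name]] *= cfg.marker_fold_change

    ref_types = [t for t in types if t not in cfg.novel_types]
    ref_props = [p for t, p in zip(types, cfg.proportions) if t not in cfg.novel_types]
    total = sum(ref_props)
    ref_props = [p / total for p in ref_props]
    ref_assign_local = _allocate(cfg.n_cells_ref, ref_types, ref_props, rng)
    ref_assign = np.asarray([types.index(ref_types[i]) for i in ref_assign_local])
    ref_counts = _draw_counts(cfg, ref_assign, mean_rows, rng)

    query_assign = _allocate(cfg.n_cells_query, types, list(cfg.proportions), rng)
    query_counts = _draw_counts(cfg, query_assign, mean_rows, rng)

    ref = CountMatrix(ref_counts, [f"ref_cell_{i}" for i in range(cfg.n_cells_ref)],
                      gene_ids)
    query = CountMatrix(query_counts,
                        [f"query_cell_{i}" for i in range(cfg.n_cells_query)],
                        list(gene_ids))
    ref_y = LabelVector(np.asarray([types[t] for t in ref_assign], dtype=object))
    query_y = LabelVector(np.asarray([types[t] for t in query_assign], dtype=object))
    return ref, ref_y, query, query_y


def make_open_set(cfg: SimulationConfig):
    """Fixture whose query contains cell types absent from the reference.

    Identical to :func:`simulate`; with empty ``novel_types`` it reduces to
    the closed-set generator.
    """
    return simulate(cfg)
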