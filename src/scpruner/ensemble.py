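"""The selector x classifier path lattice.

A *path* couples one gene selector with one classifier: the selector ranks
genes on the labeled reference, the classifier is fitted on the selected
columns.  The full lattice enumerates all 5 x 6 = 30 pairs selector-major;
its cached per-path predictions on the reference drive the pruning search,
and the pruned subset of paths is what annotates query data.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np

from . import classifiers as clf
from . import selectors as sel
from .exceptions import DegenerateDataError, IncompatibleDataError, ValidationError
from .matrix import LabelVector, NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathSpec:
    selector: sel.SelectorKind
    classifier: clf.ClassifierKind
    budget: int
    seed: int


@dataclass
class TrainedPath:
    spec: PathSpec
    selection: sel.GeneSelection
    model: clf.FittedClassifier


@dataclass
class PathPredictionMatrix:
    """Cached labels (l x n) and probabilities (l x n x k) of every path."""

    labels: np.ndarray
    probs: np.ndarray
    categories: list[str]

    @property
    def n_paths(self) -> int:
        return self.labels.shape[0]

    @property
    def n_cells(self) -> int:
        return self.labels.shape[1]

    def codes(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.categories)}
        flat = np.fromiter((lut[v] for v in self.labels.ravel()), dtype=np.int64,
                           count=self.labels.size)
        return flat.reshape(self.labels.shape)


def build_lattice(budget: int = 300, seed: int = 0) -> list[PathSpec]:
    """All selector x classifier pairs, selector-major, with derived seeds."""
    if budget < 1:
        raise ValidationError("budget must be >= 1")
    return [
        PathSpec(s, c, budget, seed + i)
        for i, (s, c) in enumerate(product(sel.SELECTOR_ORDER, clf.CLASSIFIER_ORDER))
    ]


def _path_outputs(path: TrainedPath, values: np.ndarray,
                  categories: list[str]) -> tuple[np.ndarray, np.ndarray]:
    X = values[:, path.selection.gene_indices]
    labels = clf.predict(path.model, X)
    proba = clf.predict_proba(path.model, X)
    # widen to the full label universe (a path may have seen all classes; this
    # is a no-op then, but keeps the contract if a subclass universe differs)
    if path.model.categories != categories:
        full = np.zeros((proba.shape[0], len(categories)))
        for j, c in enumerate(path.model.categories):
            full[:, categories.index(c)] = proba[:, j]
        proba = full
    return labels, proba


def train_paths(
    specs: list[PathSpec],
    ref: NormalizedMatrix,
    y: LabelVector,
    classifier_params: dict | None = None,
    detect_threshold: float = 0.0,
    out_of_fold: bool = False,
) -> tuple[list[TrainedPath], PathPredictionMatrix]:
    """Train every path on the reference and cache its reference predictions.

    By default the cached predictions are resubstitution (training-set)
    outputs — the consensus-error objective of the pruning search is defined
    on them.  ``out_of_fold=True`` instead caches 5-fold cross-fitted
    predictions, trading fidelity to the published procedure for robustness
    to overfit paths.
    """
    if ref.n_cells != len(y.labels):
        raise ValidationError("reference matrix and labels are misaligned")
    tables: dict[sel.SelectorKind, sel.GeneScoreTable] = {}
    for kind in {s.selector for s in specs}:
        if kind is sel.SelectorKind.chi2_test:
            tables[kind] = sel.chi2_scores(ref, y, detect_threshold)
        else:
            tables[kind] = sel.compute_scores(kind, ref, y)

    categories = list(y.categories)
    paths: list[TrainedPath] = []
    labels_rows, probs_rows = [], []
    for spec in specs:
        selection = sel.select_genes(tables[spec.selector], spec.budget)
        X = ref.values[:, selection.gene_indices]
        try:
            model = clf.fit(spec.classifier, X, y, spec.seed, classifier_params)
        except DegenerateDataError as exc:
            raise DegenerateDataError(
                f"path {spec.selector.value} x {spec.classifier.value}: {exc}"
            ) from exc
        path = TrainedPath(spec, selection, model)
        paths.append(path)
        if out_of_fold:
            labels, proba = _cross_fit_outputs(spec, selection, ref, y,
                                               classifier_params, categories)
        else:
            labels, proba = _path_outputs(path, ref.values, categories)
        labels_rows.append(labels)
        probs_rows.append(proba)
    preds = PathPredictionMatrix(np.vstack([r[None, :] for r in labels_rows]),
                                 np.stack(probs_rows), categories)
    return paths, preds


def _cross_fit_outputs(spec, selection, ref, y, params, categories,
                       n_folds: int = 5):
    from sklearn.model_selection import StratifiedKFold

    X = ref.values[:, selection.gene_indices]
    yarr = y.labels
    labels = np.empty(ref.n_cells, dtype=object)
    proba = np.zeros((ref.n_cells, len(categories)))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    for tr, te in skf.split(X, yarr):
        fold_y = LabelVector(yarr[tr], categories)
        model = clf.fit(spec.classifier, X[tr], fold_y, spec.seed, params)
        labels[te] = clf.predict(model, X[te])
        p = clf.predict_proba(model, X[te])
        for j, c in enumerate(model.categories):
            proba[te, categories.index(c)] = p[:, j]
    return labels, proba


def predict_paths(paths: list[TrainedPath], query: NormalizedMatrix,
                  train_gene_ids: list[str]) -> PathPredictionMatrix:
    """Apply every trained path to a query on the training gene space."""
    if query.gene_ids != train_gene_ids:
        raise IncompatibleDataError(
            "query gene space differs from the training gene space; "
            "reindex the query to the bundle's gene list first"
        )
    categories = paths[0].model.categories
    for p in paths:
        if p.model.categories != categories:
            categories = sorted(set(categories) | set(p.model.categories))
    labels_rows, probs_rows = [], []
    for path in paths:
        labels, proba = _path_outputs(path, query.values, categories)
        labels_rows.append(labels)
        probs_rows.append(proba)
    return PathPredictionMatrix(np.vstack([r[None, :] for r in labels_rows]),
                                np.stack(probs_rows), categories)


# ---------------------------------------------------------------------------
# model bundle persistence


def save_bundle(folder, paths: list[TrainedPath], gene_ids: list[str],
                categories: list[str], extra: dict | None = None) -> None:
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    manifest = {
        "categories": categories,
        "n_paths": len(paths),
        "paths": [
            {
                "index": i,
                "selector": p.spec.selector.value,
                "classifier": p.spec.classifier.value,
                "budget": p.spec.budget,
                "seed": p.spec.seed,
                "n_genes": int(len(p.selection.gene_indices)),
            }
            for i, p in enumerate(paths)
        ],
        **(extra or {}),
    }
    (folder / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (folder / "genes.txt").write_text("".join(f"{g}\n" for g in gene_ids))
    for i, p in enumerate(paths):
        sub = folder / f"path_{i:02d}"
        sub.mkdir(exist_ok=True)
        (sub / "selected_genes.txt").write_text(
            "".join(f"{gene_ids[j]}\n" for j in p.selection.gene_indices)
        )
        np.savetxt(sub / "selected_indices.txt", p.selection.gene_indices, fmt="%d")
        with open(sub / "model.pkl", "wb") as fh:
            pickle.dump(p.model, fh)


def load_bundle(folder) -> tuple[list[TrainedPath], list[str], list[str], dict]:
    folder = Path(folder)
    manifest = json.loads((folder / "manifest.json").read_text())
    gene_ids = (folder / "genes.txt").read_text().splitlines()
    paths = []
    for entry in manifest["paths"]:
        i = entry["index"]
        sub = folder / f"path_{i:02d}"
        idx = np.loadtxt(sub / "selected_indices.txt", dtype=np.intp, ndmin=1)
        with open(sub / "model.pkl", "rb") as fh:
            model = pickle.load(fh)
        spec = PathSpec(sel.SelectorKind(entry["selector"]),
                        clf.ClassifierKind(entry["classifier"]),
                        entry["budget"], entry["seed"])
        selection = sel.GeneSelection(spec.selector, idx, entry["budget"])
        paths.append(TrainedPath(spec, selection, model))
    return paths, gene_ids, manifest["categories"], manifest
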