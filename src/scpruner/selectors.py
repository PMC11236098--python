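"""Marker-gene selector bank: five per-gene ranking statistics.

Four selectors score each gene one-vs-rest per cell type (variance ratio,
Kolmogorov-Smirnov distance, 2x2 chi-square on detection, a bimodality
separation index); the fifth is a multi-class one-way ANOVA F statistic.
The statistics are used purely as ranking scores — no p-value calibration
or multiple-testing correction is applied.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, ValidationError
from .matrix import LabelVector, NormalizedMatrix

#: Floor applied wherever a variance or denominator can vanish.
EPS = 1e-8


class SelectorKind(enum.Enum):
    variance_test = "variance_test"
    ks_test = "ks_test"
    chi2_test = "chi2_test"
    bimodality = "bimodality"
    f_statistic = "f_statistic"


#: Fixed enumeration order of the selector bank.
SELECTOR_ORDER: tuple[SelectorKind, ...] = (
    SelectorKind.variance_test,
    SelectorKind.ks_test,
    SelectorKind.chi2_test,
    SelectorKind.bimodality,
    SelectorKind.f_statistic,
)


@dataclass
class GeneScoreTable:
    """Scores per gene: one row per class (one-vs-rest) or a single row."""

    selector: SelectorKind
    scores: np.ndarray  # (k, m) or (1, m)
    classes: list[str] | None  # None for single-row (multi-class) tables


@dataclass
class GeneSelection:
    selector: SelectorKind
    gene_indices: np.ndarray  # sorted unique
    budget: int


def _class_masks(y: LabelVector) -> list[np.ndarray]:
    codes = y.codes()
    return [codes == c for c in range(y.n_classes)]


def _require_min_cells(y: LabelVector, minimum: int) -> None:
    for cat, mask in zip(y.categories, _class_masks(y)):
        if mask.sum() < minimum:
            raise DegenerateDataError(
                f"class {cat!r} has {int(mask.sum())} cells; needs >= {minimum}"
            )


def variance_test_scores(M: NormalizedMatrix, y: LabelVector) -> GeneScoreTable:
    """One-vs-rest log variance-ratio score.

    Per class c and gene: W = s2_class / s2_rest (sample variances, floored at
    EPS) and the score is |(n-1) * ln(W)| / df with df = k - 1.
    """
    _require_min_cells(y, 2)
    X = M.values
    n = X.shape[0]
    df = y.n_classes - 1
    rows = []
    for mask in _class_masks(y):
        s2_in = X[mask].var(axis=0, ddof=1)
        s2_out = X[~mask].var(axis=0, ddof=1)
        W = np.maximum(s2_in, EPS) / np.maximum(s2_out, EPS)
        rows.append(np.abs((n - 1) * np.log(W)) / df)
    return GeneScoreTable(SelectorKind.variance_test, np.vstack(rows), list(y.categories))


def ks_scores(M: NormalizedMatrix, y: LabelVector) -> GeneScoreTable:
    """One-vs-rest two-sample Kolmogorov-Smirnov statistic per gene."""
    _require_min_cells(y, 1)
    X = M.values
    rows = []
    for mask in _class_masks(y):
        xin, xout = X[mask], X[~mask]
        row = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            row[j] = stats.ks_2samp(xin[:, j], xout[:, j], method="asymp").statistic
        rows.append(row)
    return GeneScoreTable(SelectorKind.ks_test, np.vstack(rows), list(y.categories))


def chi2_scores(M: NormalizedMatrix, y: LabelVector,
                detect_threshold: float = 0.0) -> GeneScoreTable:
    """One-vs-rest chi-square on the 2x2 detection table.

    Expression is binarized as detected (value > detect_threshold) vs not;
    the score is sum (O - E)^2 / E over the four cells of the
    {class, rest} x {detected, not} table, no continuity correction.
    Genes with a zero margin (always or never detected) score 0.
    """
    if detect_threshold < 0:
        raise ValidationError("detect_threshold must be >= 0")
    detected = M.values > detect_threshold
    n = detected.shape[0]
    total_det = detected.sum(axis=0)
    rows = []
    for mask in _class_masks(y):
        n1 = int(mask.sum())
        n2 = n - n1
        a = detected[mask].sum(axis=0)           # class, detected
        b = total_det - a                        # rest, detected
        c = n1 - a                               # class, not detected
        d = n2 - b                               # rest, not detected
        col_det = a + b
        col_not = c + d
        denom = n1 * n2 * col_det * col_not
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = n * (a * d - b * c) ** 2 / denom
        rows.append(np.where(denom == 0, 0.0, chi2))
    return GeneScoreTable(SelectorKind.chi2_test, np.vstack(rows), list(y.categories))


def bimodality_scores(M: NormalizedMatrix, y: LabelVector) -> GeneScoreTable:
    """One-vs-rest separation index |mean_x - mean_y| / (p_x s_x + p_y s_y)."""
    _require_min_cells(y, 2)
    X = M.values
    n = X.shape[0]
    rows = []
    for mask in _class_masks(y):
        xin, xout = X[mask], X[~mask]
        p_in = mask.sum() / n
        p_out = 1.0 - p_in
        num = np.abs(xin.mean(axis=0) - xout.mean(axis=0))
        den = p_in * xin.std(axis=0, ddof=1) + p_out * xout.std(axis=0, ddof=1) + EPS
        rows.append(num / den)
    return GeneScoreTable(SelectorKind.bimodality, np.vstack(rows), list(y.categories))


def f_statistic_scores(M: NormalizedMatrix, y: LabelVector) -> GeneScoreTable:
    """One-way ANOVA F statistic per gene (single-row, multi-class).

    F = (SSB/df1) / (SSW/df2) with df1 = k - 1, df2 = n - k; SSW is floored
    at EPS so perfectly separated genes get a large finite score.
    """
    X = M.values
    n, k = X.shape[0], y.n_classes
    if n <= k:
        raise DegenerateDataError(f"need more cells ({n}) than classes ({k})")
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    for mask in _class_masks(y):
        nc = int(mask.sum())
        if nc == 0:
            raise DegenerateDataError("empty class in label vector")
        ssb += nc * (X[mask].mean(axis=0) - grand) ** 2
    sst = ((X - grand) ** 2).sum(axis=0)
    ssw = np.maximum(sst - ssb, 0.0)
    df1, df2 = k - 1, n - k
    F = (ssb / df1) / (np.maximum(ssw, EPS) / df2)
    return GeneScoreTable(SelectorKind.f_statistic, F[None, :], None)


_SCORERS = {
    SelectorKind.variance_test: variance_test_scores,
    SelectorKind.ks_test: ks_scores,
    SelectorKind.chi2_test: chi2_scores,
    SelectorKind.bimodality: bimodality_scores,
    SelectorKind.f_statistic: f_statistic_scores,
}


def compute_scores(kind: SelectorKind, M: NormalizedMatrix,
                   y: LabelVector) -> GeneScoreTable:
    return _SCORERS[kind](M, y)


def _top_indices(scores: np.ndarray, budget: int) -> np.ndarray:
    # stable sort on -scores breaks ties toward the lower gene index
    order = np.argsort(-scores, kind="stable")
    return order[:budget]


def select_genes(table: GeneScoreTable, budget: int = 300) -> GeneSelection:
    """Top-``budget`` genes per class (union) or overall for single-row tables.

    Ties break toward the lower gene index; a union smaller than two genes
    falls back to the top two genes by the per-gene maximum score.
    """
    if budget < 1:
        raise ValidationError("budget must be >= 1")
    m = table.scores.shape[1]
    if budget > m:
        warnings.warn(f"budget {budget} exceeds {m} genes; clipping", stacklevel=2)
        budget = m
    chosen: set[int] = set()
    for row in table.scores:
        chosen.update(_top_indices(row, budget).tolist())
    if len(chosen) < 2:
        chosen = set(_top_indices(table.scores.max(axis=0), 2).tolist())
    return GeneSelection(table.selector, np.asarray(sorted(chosen), dtype=np.intp), budget)


def score_table_to_tsv(table: GeneScoreTable, gene_ids: list[str], path) -> None:
    """Write (selector, class, gene, score) rows."""
    with open(path, "w") as fh:
        fh.write("selector\tclass\tgene\tscore\n")
        classes = table.classes or ["*"]
        for cls, row in zip(classes, table.scores):
            for g, s in zip(gene_ids, row):
                fh.write(f"{table.selector.value}\t{cls}\t{g}\t{s:.10g}\n")
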