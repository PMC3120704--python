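"""AIC/dAIC selection of the number of clusters.

Each clustering solution is scored under a per-cluster Bernoulli model: for
nonempty cluster c and annotation column j the maximum-likelihood carrier
rate is theta(c, j) = (ones in c for column j) / |c|, and the log-likelihood
sums ln theta or ln(1 - theta) cell by cell (0 ln 0 = 0). The score is

    AIC = 2 p - 2 lnL,    p = (number of nonempty clusters) x (columns scored)

with smaller better. Because most annotation columns are distributed at
random across clusters, plain AIC is dominated by those columns and tends to
favour very few clusters; dAIC therefore rescores each level on only the
columns whose per-column AIC improves, relative to the one-cluster solution,
in at least one multi-cluster solution (default: solutions with more than
two clusters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .clustering import ClusteringLevel
from .io import AnnotationMatrix


@dataclass(frozen=True)
class ModelScore:
    """AIC/dAIC score of one clustering level."""

    level_k: int
    log_likelihood: float
    n_parameters: int
    aic: float
    daic: float | None = None
    retained_dimensions: frozenset[str] | None = None

    def __post_init__(self):
        if self.log_likelihood > 1e-9:
            raise ValueError("Bernoulli log-likelihood cannot be positive")
        expected = 2 * self.n_parameters - 2 * self.log_likelihood
        if abs(self.aic - expected) > 1e-6 * max(1.0, abs(expected)):
            raise ValueError("aic must equal 2*n_parameters - 2*log_likelihood")


def _column_indices(matrix: AnnotationMatrix, dimensions) -> np.ndarray:
    if dimensions is None:
        return np.arange(matrix.n_annotations)
    wanted = set(dimensions)
    if not wanted:
        raise ValueError("empty dimension subset")
    idx = [j for j, a in enumerate(matrix.annotations) if a in wanted]
    missing = wanted - {matrix.annotations[j] for j in idx}
    if missing:
        raise ValueError(f"unknown dimensions: {sorted(missing)[:5]}")
    return np.asarray(idx, dtype=np.int64)


def _cluster_blocks(matrix: AnnotationMatrix, assignment: dict[str, int]):
    not_covered = [g for g in matrix.genes if g not in assignment]
    if not_covered:
        raise ValueError(
            f"assignment does not cover matrix genes: {not_covered[:5]}"
        )
    labels = np.array([assignment[g] for g in matrix.genes])
    for c in np.unique(labels):
        yield matrix.incidence[labels == c, :]


def _loglik_terms(block: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Per-column maximized Bernoulli log-likelihood within one cluster."""
    sub = block[:, cols].astype(np.float64)
    size = sub.shape[0]
    ones = sub.sum(axis=0)
    theta = ones / size
    # xlogy implements the 0 ln 0 = 0 convention for degenerate rates
    return xlogy(ones, theta) + xlogy(size - ones, 1.0 - theta)


def bernoulli_loglik(
    matrix: AnnotationMatrix, assignment: dict[str, int], dimensions=None
) -> float:
    """Maximized log-likelihood under the per-cluster Bernoulli model.

    ``dimensions`` restricts scoring to a subset of annotation columns;
    ``None`` scores all columns. Degenerate rates theta in {0, 1} contribute
    zero (the 0 ln 0 = 0 convention).
    """
    cols = _column_indices(matrix, dimensions)
    total = 0.0
    for block in _cluster_blocks(matrix, assignment):
        total += float(_loglik_terms(block, cols).sum())
    return total


def aic_level(
    matrix: AnnotationMatrix,
    assignment: dict[str, int],
    dimensions=None,
    level_k: int | None = None,
) -> ModelScore:
    """AIC of one clustering solution on the scored columns.

    Parameters are counted only for nonempty clusters: an empty cluster fits
    no rates. ``level_k`` labels the score with the requested k; when omitted
    it is inferred as the largest assigned index + 1.
    """
    cols = _column_indices(matrix, dimensions)
    lnl = bernoulli_loglik(matrix, assignment, dimensions)
    n_nonempty = len(set(assignment[g] for g in matrix.genes))
    n_params = n_nonempty * len(cols)
    if level_k is None:
        level_k = max(assignment.values()) + 1 if assignment else 1
    return ModelScore(
        level_k=level_k,
        log_likelihood=lnl,
        n_parameters=n_params,
        aic=2.0 * n_params - 2.0 * lnl,
    )


def aic_per_dimension(
    matrix: AnnotationMatrix, assignment: dict[str, int], dimension: str
) -> float:
    """AIC of a single annotation column under the partition."""
    cols = _column_indices(matrix, [dimension])
    lnl = 0.0
    n_clusters = 0
    for block in _cluster_blocks(matrix, assignment):
        n_clusters += 1
        lnl += float(_loglik_terms(block, cols).sum())
    return 2.0 * n_clusters - 2.0 * lnl


def daic_dimension_filter(
    matrix: AnnotationMatrix,
    levels: list[ClusteringLevel],
    min_k_filter: int = 3,
) -> frozenset[str]:
    """Select the columns that are distributed non-randomly in some solution.

    A column is retained iff its per-column AIC in at least one solution with
    ``k_requested >= min_k_filter`` is smaller than its per-column AIC in the
    one-cluster solution. Randomly distributed columns fail this test because
    splitting buys them no likelihood, while each split costs parameters.
    """
    by_k = {lv.k_requested: lv for lv in levels}
    if 1 not in by_k:
        raise ValueError("levels must include the k=1 solution")
    candidates = [lv for lv in levels if lv.k_requested >= min_k_filter]
    base = by_k[1]
    retained = []
    # vectorized per-column AIC across all columns at once
    base_aic = _per_dimension_aic_all(matrix, base.assignment)
    if candidates:
        best = np.full(matrix.n_annotations, np.inf)
        for lv in candidates:
            best = np.minimum(best, _per_dimension_aic_all(matrix, lv.assignment))
        retained = [a for j, a in enumerate(matrix.annotations) if best[j] < base_aic[j]]
    return frozenset(retained)


def _per_dimension_aic_all(
    matrix: AnnotationMatrix, assignment: dict[str, int]
) -> np.ndarray:
    cols = np.arange(matrix.n_annotations)
    lnl = np.zeros(matrix.n_annotations)
    n_clusters = 0
    for block in _cluster_blocks(matrix, assignment):
        n_clusters += 1
        lnl += _loglik_terms(block, cols)
    return 2.0 * n_clusters - 2.0 * lnl


def daic_scores(
    matrix: AnnotationMatrix,
    levels: list[ClusteringLevel],
    retained_dimensions,
) -> list[ModelScore]:
    """Score every level (including k=1) on the retained columns only."""
    retained = frozenset(retained_dimensions)
    if not retained:
        raise ValueError("empty retained dimension set")
    scores = []
    for lv in levels:
        s = aic_level(matrix, lv.assignment, retained, level_k=lv.k_requested)
        scores.append(
            ModelScore(
                level_k=lv.k_requested,
                log_likelihood=s.log_likelihood,
                n_parameters=s.n_parameters,
                aic=s.aic,
                daic=s.aic,
                retained_dimensions=retained,
            )
        )
    return scores


def select_best_level(scores: list[ModelScore], use_daic: bool = False) -> int:
    """Return the level_k with the minimal (d)AIC score; ties prefer smaller k."""
    if not scores:
        raise ValueError("no scores to select from")
    def key(s: ModelScore):
        value = s.daic if use_daic else s.aic
        if value is None:
            raise ValueError(f"level {s.level_k} has no dAIC score")
        return (value, s.level_k)
    return min(scores, key=key).level_k
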