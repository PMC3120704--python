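"""NMF clustering of binary annotation matrices.

Genes are partitioned into k groups for every k in 1..k_max by factorizing
the binary gene x annotation incidence matrix V into non-negative loadings
W (gene x k) and H (k x annotation) under the generalized Kullback-Leibler
divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ],

minimized by Lee-Seung multiplicative updates. KL suits sparse binary counts,
and factor-based clustering lets a cluster be defined by a small subset of
annotation columns. Each gene is hard-assigned to the component with maximal
loading. Levels are computed independently of each other — level k+1 is not
a refinement of level k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AnnotationMatrix

_EPS = np.finfo(np.float64).tiny


@dataclass
class ClusteringLevel:
    """One clustering solution: a disjoint, covering partition into k groups.

    ``assignment`` maps every clustered gene to a cluster index in
    ``[0, k_requested)``. Clusters are allowed to come out empty
    (``n_nonempty < k_requested``); downstream consumers skip empty clusters.
    """

    k_requested: int
    assignment: dict[str, int]
    objective: float
    seed: int
    n_restarts_used: int

    def __post_init__(self):
        if self.k_requested < 1:
            raise ValueError("k_requested must be >= 1")
        if self.objective < 0:
            raise ValueError("objective must be non-negative")
        bad = [g for g, c in self.assignment.items() if not 0 <= c < self.k_requested]
        if bad:
            raise ValueError(f"cluster index out of range for genes {bad[:5]}")

    @property
    def n_nonempty(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cluster: int) -> set[str]:
        return {g for g, c in self.assignment.items() if c == cluster}

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.assignment.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def nonempty_clusters(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def labels(self, genes) -> np.ndarray:
        return np.array([self.assignment[g] for g in genes], dtype=np.int64)


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    div = float(np.sum(WH) - np.sum(V))
    div += float(np.sum(V[mask] * np.log(V[mask] / WH[mask])))
    return max(div, 0.0)  # divergence is >= 0; clamp float round-off


def _mu_kl_fit(
    V: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """One multiplicative-update run from a random non-negative init.

    Init entries are uniform on (0, 1] scaled so the product WH matches the
    data mean. Stops when the relative objective decrease falls below tol.
    """
    n, m = V.shape
    scale = np.sqrt(max(V.mean(), _EPS) / k)
    W = scale * (1.0 - rng.random((n, k)))  # uniform on (0, 1]
    H = scale * (1.0 - rng.random((k, m)))
    row_ones = np.ones(n)
    col_ones = np.ones(m)
    prev = np.inf
    obj = _kl_divergence(V, W @ H + _EPS)
    for _ in range(max_iter):
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / np.maximum(np.outer(row_ones, H.sum(axis=1)), _EPS)
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / np.maximum(np.outer(W.sum(axis=0), col_ones), _EPS)
        prev, obj = obj, _kl_divergence(V, W @ H + _EPS)
        if prev - obj < tol * max(abs(prev), 1.0):
            break
    return W, H, obj


def nmf_factorize(
    matrix: AnnotationMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    restarts: int = 10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Factorize the incidence matrix into non-negative loadings of rank k.

    Runs ``restarts`` multiplicative-update fits from random initializations
    seeded ``seed, seed + 1, ...`` and returns the ``(W, H, objective)`` of
    the run with the lowest final generalized KL divergence.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > matrix.n_genes:
        raise ValueError(f"k={k} exceeds number of genes ({matrix.n_genes})")
    V = matrix.incidence.astype(np.float64)
    if not V.any():
        raise ValueError("all-zero incidence matrix cannot be factorized")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        W, H, obj = _mu_kl_fit(V, k, rng, max_iter=max_iter, tol=tol)
        if best is None or obj < best[2]:
            best = (W, H, obj)
    return best


def assign_clusters(gene_loadings: np.ndarray, genes) -> dict[str, int]:
    """Hard-assign each gene to the component with maximal loading.

    Ties (including an all-zero loading row) break toward the lowest
    component index, matching numpy argmax.
    """
    W = np.asarray(gene_loadings, dtype=np.float64)
    if (W < 0).any():
        raise ValueError("gene loadings must be non-negative")
    labels = W.argmax(axis=1)
    return {g: int(c) for g, c in zip(genes, labels)}


def build_levels(
    matrix: AnnotationMatrix,
    k_max: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    restarts: int = 10,
) -> list[ClusteringLevel]:
    """Compute independent clustering solutions for every k in 1..k_max.

    Each level is its own factorization (no splitting of parent clusters);
    level 1 trivially holds the whole gene set. The per-level seed is
    ``seed + (k - 1) * restarts`` so that levels use disjoint restart seeds
    and the whole ladder is reproducible from the single ``seed``.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > matrix.n_genes:
        raise ValueError(f"k_max={k_max} exceeds number of genes ({matrix.n_genes})")
    levels = []
    for k in range(1, k_max + 1):
        level_seed = seed + (k - 1) * restarts
        if k == 1:
            assignment = {g: 0 for g in matrix.genes}
            V = matrix.incidence.astype(np.float64)
            if not V.any():
                raise ValueError("all-zero incidence matrix cannot be factorized")
            # rank-1 KL optimum is closed-form (outer product of margins), but
            # running the factorization keeps the objective comparable
            W, H, obj = nmf_factorize(
                matrix, 1, seed=level_seed, max_iter=max_iter, tol=tol,
                restarts=restarts,
            )
        else:
            W, H, obj = nmf_factorize(
                matrix, k, seed=level_seed, max_iter=max_iter, tol=tol,
                restarts=restarts,
            )
            assignment = assign_clusters(W, matrix.genes)
        levels.append(
            ClusteringLevel(
                k_requested=k,
                assignment=assignment,
                objective=obj,
                seed=level_seed,
                n_restarts_used=restarts,
            )
        )
    return levels
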