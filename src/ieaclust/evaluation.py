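"""Benchmark computations on planted-partition data.

Every function here recomputes a headline property of the method from
scratch on synthetic data: clustering recovery, dAIC cluster-number
selection, noise-column filtering, IEA power and type-I error, oracle
agreement of the statistical primitives, and end-to-end determinism. The
problem sizes are the package's standard study conditions (200 genes, four
planted clusters, p_in = 0.9, p_out = 0.05; 500 genes for the filter
benchmarks) so a full sweep runs in minutes on one CPU.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .clustering import build_levels, nmf_factorize, assign_clusters
from .enrichment import bh_fdr, enrich_clusters
from .io import AnnotationMatrix
from .model_selection import daic_dimension_filter, daic_scores, select_best_level
from .synthetic import SyntheticParams, adjusted_rand_index, generate

ALPHA_IEA = 0.1


def _dataset_seed(base_seed: int, rep: int) -> int:
    # keep derived seeds well below 2**31
    return (base_seed * 10_007 + rep * 101) % (2**31 - 1)


def clustering_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    p_in: float = 0.9,
    p_out: float = 0.05,
    n_genes: int = 200,
    k_true: int = 4,
    restarts: int = 10,
) -> float:
    """Mean adjusted Rand index of the k = k_true solution over datasets."""
    aris = []
    for rep in range(n_seeds):
        seed = _dataset_seed(base_seed, rep)
        ds = generate(
            SyntheticParams(
                n_genes=n_genes, k_true=k_true, p_in=p_in, p_out=p_out, seed=seed
            )
        )
        W, _, _ = nmf_factorize(ds.system_one, k_true, seed=seed + 1, restarts=restarts)
        assignment = assign_clusters(W, ds.system_one.genes)
        aris.append(adjusted_rand_index(assignment, ds.partition))
    return float(np.mean(aris))


def noiseless_recovery(base_seed: int = 0, k_true: int = 4) -> float:
    """ARI on noiseless planted blocks (p_in = 1, p_out = 0)."""
    ds = generate(
        SyntheticParams(p_in=1.0, p_out=0.0, k_true=k_true, seed=_dataset_seed(base_seed, 0))
    )
    W, _, _ = nmf_factorize(ds.system_one, k_true, seed=base_seed + 1, restarts=10)
    assignment = assign_clusters(W, ds.system_one.genes)
    return adjusted_rand_index(assignment, ds.partition)


def daic_selection_rate(
    n_seeds: int = 20, base_seed: int = 0, k_max: int = 6, k_true: int = 4
) -> float:
    """Fraction of datasets where argmin dAIC lies within +-1 of k_true."""
    hits = 0
    for rep in range(n_seeds):
        seed = _dataset_seed(base_seed, rep)
        ds = generate(SyntheticParams(k_true=k_true, seed=seed))
        levels = build_levels(ds.system_one, k_max, seed=seed + 1)
        retained = daic_dimension_filter(ds.system_one, levels)
        if not retained:
            retained = frozenset(ds.system_one.annotations)
        scores = daic_scores(ds.system_one, levels, retained)
        best = select_best_level(scores, use_daic=True)
        hits += abs(best - k_true) <= 1
    return hits / n_seeds


def _with_noise_columns(
    matrix: AnnotationMatrix, n_noise: int, rate: float, rng: np.random.Generator
) -> tuple[AnnotationMatrix, set[str]]:
    noise = (rng.random((matrix.n_genes, n_noise)) < rate).astype(np.int8)
    noise_names = [f"noise{j}" for j in range(n_noise)]
    combined = AnnotationMatrix(
        matrix.system_label,
        matrix.genes,
        tuple(list(matrix.annotations) + noise_names),
        np.hstack([matrix.incidence, noise]),
    )
    return combined, set(noise_names)


def noise_filter_removed_fraction(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_genes: int = 500,
    n_noise: int = 30,
    noise_rate: float = 0.3,
    k_max: int = 6,
    in_matrix: bool = False,
    restarts: int = 5,
) -> float:
    """Mean fraction of pure-noise Bernoulli columns removed by the dAIC filter.

    With ``in_matrix=False`` (primary) the clustering levels are fit on the
    planted annotation system alone and the noise columns are scored against
    those solutions — the filter's specificity on columns carrying no cluster
    signal. With ``in_matrix=True`` the noise columns also enter the
    clustering, so solutions above the true cluster count partly adapt to
    them and retention rises; both numbers are reported by the acceptance
    script.
    """
    fractions = []
    for rep in range(n_seeds):
        seed = _dataset_seed(base_seed, rep)
        ds = generate(SyntheticParams(n_genes=n_genes, seed=seed))
        rng = np.random.default_rng(seed + 7)
        combined, noise_names = _with_noise_columns(
            ds.system_one, n_noise, noise_rate, rng
        )
        cluster_input = combined if in_matrix else ds.system_one
        levels = build_levels(cluster_input, k_max, seed=seed + 1, restarts=restarts)
        retained = daic_dimension_filter(combined, levels)
        removed = len(noise_names - retained)
        fractions.append(removed / len(noise_names))
    return float(np.mean(fractions))


def _iea_records_for_dataset(ds, seed: int, restarts: int = 10):
    k = ds.params.k_true
    W, _, _ = nmf_factorize(ds.system_one, k, seed=seed, restarts=restarts)
    assignment = assign_clusters(W, ds.system_one.genes)
    from .clustering import ClusteringLevel

    level = ClusteringLevel(
        k_requested=k, assignment=assignment, objective=0.0, seed=seed,
        n_restarts_used=restarts,
    )
    return level, enrich_clusters(level, ds.system_two, ds.gene_list, mode="IEA")


def iea_null_fdr_fraction(n_seeds: int = 50, base_seed: int = 0) -> float:
    """Type-I proxy: mean fraction of IEA tests called at FDR < 0.1 when the
    second annotation system is uncoupled from the clustered partition."""
    fractions = []
    for rep in range(n_seeds):
        seed = _dataset_seed(base_seed, rep)
        ds = generate(SyntheticParams(coupling=0.0, seed=seed))
        _, records = _iea_records_for_dataset(ds, seed + 1)
        if records:
            fractions.append(
                sum(r.p_fdr < ALPHA_IEA for r in records) / len(records)
            )
        else:
            fractions.append(0.0)
    return float(np.mean(fractions))


def iea_power_detection_rate(n_seeds: int = 50, base_seed: int = 0) -> float:
    """Power: fraction of coupled datasets where every planted cluster has its
    cross-system signal annotation enriched at FDR < 0.1 in some cluster."""
    hits = 0
    for rep in range(n_seeds):
        seed = _dataset_seed(base_seed, rep)
        ds = generate(SyntheticParams(coupling=1.0, seed=seed))
        _, records = _iea_records_for_dataset(ds, seed + 1)
        significant = {r.annotation for r in records if r.p_fdr < ALPHA_IEA}
        detected_all = all(
            any(a in significant for a in ds.signal_annotations(2, c))
            for c in range(ds.params.k_true)
        )
        hits += detected_all
    return hits / n_seeds


def fisher_oracle_max_rel_error(max_population: int = 60) -> float:
    """Worst relative disagreement between the Fisher tail and exact
    integer-arithmetic enumeration over every valid table with N <= ``max_population``."""
    worst = 0.0
    for N in range(1, max_population + 1):
        for n in range(1, N + 1):
            for K in range(0, N + 1):
                a_min = max(0, n + K - N)
                a_max = min(n, K)
                terms = [math.comb(K, x) * math.comb(N - K, n - x)
                         for x in range(a_min, a_max + 1)]
                total = math.comb(N, n)
                # suffix sums give P(X >= a) exactly
                suffix = 0
                exact = {}
                for x in range(a_max, a_min - 1, -1):
                    suffix += terms[x - a_min]
                    exact[x] = suffix / total
                a_values = np.arange(a_min, a_max + 1)
                got = hypergeom.sf(a_values - 1, N, K, n)
                for x, g in zip(a_values, got):
                    e = exact[int(x)]
                    worst = max(worst, abs(g - e) / e)
    return worst


def bh_oracle_max_abs_error(n_vectors: int = 1000, base_seed: int = 0) -> float:
    """Worst absolute disagreement between bh_fdr and a literal step-up rule."""

    def stepup(p: np.ndarray) -> np.ndarray:
        m = p.size
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        out = np.empty(m)
        out[order] = adj
        return out

    rng = np.random.default_rng(base_seed)
    worst = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 60))
        p = rng.random(m).clip(1e-12, 1.0)
        worst = max(worst, float(np.max(np.abs(bh_fdr(p) - stepup(p)))))
    return worst


def pipeline_determinism(tmp_dir, base_seed: int = 0) -> bool:
    """Run the full pipeline twice with one seed; outputs must be byte-identical."""
    from .pipeline import RunConfig, run_pipeline
    from .synthetic import write_dataset

    tmp_dir = Path(tmp_dir)
    ds = generate(SyntheticParams(seed=_dataset_seed(base_seed, 0)))
    inputs = write_dataset(ds, tmp_dir / "inputs")
    outputs = []
    for run_idx in (1, 2):
        out = tmp_dir / f"run{run_idx}"
        config = RunConfig(
            gene_list_path=inputs["genes"],
            system_one_path=inputs["system_one"],
            system_two_path=inputs["system_two"],
            out_dir=str(out),
            k_max=5,
            seed=base_seed + 17,
        )
        result = run_pipeline(config)
        outputs.append(
            {name: Path(p).read_bytes() for name, p in result.output_paths.items()}
        )
    return outputs[0] == outputs[1]
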