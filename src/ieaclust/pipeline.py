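"""End-to-end analysis: cluster a gene list in two annotation systems and
cross-evaluate the clusters.

The flow mirrors how the method is used on a differential-expression gene
list: restrict each annotation matrix to the list, build independent NMF
clusterings for k = 1..k_max per system, score levels with AIC and dAIC,
assemble the two cluster trees, run DEA and IEA enrichment at every level
(plus list-vs-genome at the root when a genome background is supplied), and
compute inter-correlation between the best dAIC levels of the two trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as _io
from .clustering import build_levels
from .enrichment import (
    MODE_DEA,
    MODE_IEA,
    enrich_clusters,
    enrich_list_vs_genome,
    inter_correlation,
)
from .io import AnnotationMatrix, GeneList, restrict_to_list
from .model_selection import (
    aic_level,
    daic_dimension_filter,
    daic_scores,
    select_best_level,
)
from .tree import ClusterTree, build_tree

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one analysis run."""

    gene_list_path: str
    system_one_path: str
    system_two_path: str
    out_dir: str
    system_one_label: str = "GO"
    system_two_label: str = "TF"
    genome_one_path: str | None = None
    genome_two_path: str | None = None
    k_max: int = 10
    seed: int = 0
    restarts: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    min_k_filter: int = 3
    alpha: float = 0.1
    fdr_family: str = "level"

    def __post_init__(self):
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class SystemResult:
    """Everything computed for one annotation system's tree."""

    matrix: AnnotationMatrix
    tree: ClusterTree
    retained_dimensions: frozenset[str]
    dea_records: list = field(default_factory=list)
    iea_records: list = field(default_factory=list)
    list_vs_genome_records: list = field(default_factory=list)


@dataclass
class PipelineResult:
    gene_list: GeneList
    systems: dict[str, SystemResult]
    inter_correlation: list
    output_paths: dict[str, str]


def _read_matrix(path: str, label: str) -> AnnotationMatrix:
    if str(path).endswith(".gmt"):
        return _io.read_gmt(path, label)
    return _io.read_pairs_tsv(path, label)


def analyze_system(
    matrix: AnnotationMatrix, config: RunConfig, seed: int
) -> tuple[ClusterTree, frozenset[str]]:
    """Cluster one restricted matrix for k = 1..k_max and score the levels."""
    k_max = min(config.k_max, matrix.n_genes)
    if k_max < config.k_max:
        logger.warning(
            "%s: k_max reduced to %d (only %d annotated genes)",
            matrix.system_label, k_max, matrix.n_genes,
        )
    levels = build_levels(
        matrix,
        k_max,
        seed=seed,
        max_iter=config.max_iter,
        tol=config.tol,
        restarts=config.restarts,
    )
    aic = [
        aic_level(matrix, lv.assignment, level_k=lv.k_requested) for lv in levels
    ]
    retained = daic_dimension_filter(matrix, levels, config.min_k_filter)
    if not retained:
        logger.warning(
            "%s: dAIC filter retained no dimensions; falling back to all "
            "%d columns (dAIC = AIC)",
            matrix.system_label, matrix.n_annotations,
        )
        retained = frozenset(matrix.annotations)
    logger.info(
        "%s: dAIC filter retained %d of %d dimensions",
        matrix.system_label, len(retained), matrix.n_annotations,
    )
    daic = daic_scores(matrix, levels, retained)
    # merge: keep AIC from the full-dimension score, dAIC from the filtered one
    scores = [
        type(a)(
            level_k=a.level_k,
            log_likelihood=a.log_likelihood,
            n_parameters=a.n_parameters,
            aic=a.aic,
            daic=d.daic,
            retained_dimensions=d.retained_dimensions,
        )
        for a, d in zip(aic, daic)
    ]
    best_aic = select_best_level(scores, use_daic=False)
    best_daic = select_best_level(scores, use_daic=True)
    logger.info(
        "%s: best level by AIC = %d, by dAIC = %d",
        matrix.system_label, best_aic, best_daic,
    )
    tree = build_tree(
        matrix.system_label,
        levels,
        scores,
        universe=matrix.genes,
        best_aic_level=best_aic,
        best_daic_level=best_daic,
    )
    return tree, retained


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write result files to ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("seed = %d", config.seed)

    gene_list = _io.read_gene_list(config.gene_list_path)
    labels = (config.system_one_label, config.system_two_label)
    if labels[0] == labels[1]:
        raise ValueError("the two annotation systems need distinct labels")
    matrices = {
        labels[0]: restrict_to_list(
            _read_matrix(config.system_one_path, labels[0]), gene_list
        ),
        labels[1]: restrict_to_list(
            _read_matrix(config.system_two_path, labels[1]), gene_list
        ),
    }

    systems: dict[str, SystemResult] = {}
    for offset, label in enumerate(labels):
        tree, retained = analyze_system(
            matrices[label], config, seed=config.seed + offset * 100_000
        )
        systems[label] = SystemResult(
            matrix=matrices[label], tree=tree, retained_dimensions=retained
        )

    # DEA (same system) and IEA (other system) at every level of each tree
    for label, other in (labels, labels[::-1]):
        result = systems[label]
        for lv in result.tree.levels:
            result.dea_records.extend(
                enrich_clusters(
                    lv, matrices[label], gene_list, MODE_DEA, config.fdr_family
                )
            )
            result.iea_records.extend(
                enrich_clusters(
                    lv, matrices[other], gene_list, MODE_IEA, config.fdr_family
                )
            )

    for label, genome_path in (
        (labels[0], config.genome_one_path),
        (labels[1], config.genome_two_path),
    ):
        if genome_path:
            genome = _read_matrix(genome_path, label)
            systems[label].list_vs_genome_records = enrich_list_vs_genome(
                gene_list, genome
            )

    tree_a = systems[labels[0]].tree
    tree_b = systems[labels[1]].tree
    inter = inter_correlation(
        tree_a.level(tree_a.best_daic_level),
        tree_b.level(tree_b.best_daic_level),
    )

    paths: dict[str, str] = {}
    for label in labels:
        result = systems[label]
        tree_path = out_dir / f"tree_{label}.json"
        _io.write_tree_json(result.tree, tree_path)
        paths[f"tree_{label}"] = str(tree_path)
        enr_path = out_dir / f"enrichment_{label}.tsv"
        _io.write_enrichment_tsv(
            result.dea_records + result.iea_records + result.list_vs_genome_records,
            enr_path,
        )
        paths[f"enrichment_{label}"] = str(enr_path)
    inter_path = out_dir / "inter_correlation.tsv"
    write_intercorrelation_tsv(inter, inter_path)
    paths["inter_correlation"] = str(inter_path)

    return PipelineResult(
        gene_list=gene_list,
        systems=systems,
        inter_correlation=inter,
        output_paths=paths,
    )


INTERCORR_COLUMNS = [
    "level_a",
    "cluster_a",
    "size_a",
    "level_b",
    "cluster_b",
    "size_b",
    "overlap",
    "universe_size",
    "p_raw",
    "p_fdr",
]


def write_intercorrelation_tsv(records, path) -> None:
    """Write inter-correlation records sorted by adjusted p."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(INTERCORR_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        str(r.level_a),
                        str(r.cluster_a),
                        str(r.size_a),
                        str(r.level_b),
                        str(r.cluster_b),
                        str(r.size_b),
                        str(r.overlap),
                        str(r.universe_size),
                        _io.format_p(r.p_raw),
                        _io.format_p(r.p_fdr),
                    ]
                )
                + "\n"
            )
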