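"""Fisher's-exact-test enrichment with Benjamini-Hochberg FDR control.

Three test configurations share one 2x2 construction:

* list vs genome — the classical over-representation test of the whole gene
  list against a genome background ("List p-value");
* DEA (dependent enrichment analysis) — a cluster tested against the gene
  list in the SAME annotation system used for clustering. Because the
  clustering variable and the tested variable coincide, these p-values are
  circular as tests and are reported only as relative enrichment scores;
* IEA (independent enrichment analysis) — a cluster tested against the gene
  list in the OTHER annotation system. Clustering and testing variables are
  independent, so these p-values carry their usual inferential meaning; IEA
  is the statistic this package exists for.

All p-values are one-sided over-representation tails of the hypergeometric
distribution, equivalently one-sided Fisher tests on
``[a, n - a; K - a, N - n - K + a]``, corrected within an analysis family by
the BH step-up rule. Cross-tree cluster association (inter-correlation) uses
the same machinery on gene-membership overlap tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .clustering import ClusteringLevel
from .io import AnnotationMatrix, GeneList

MODE_DEA = "DEA"
MODE_IEA = "IEA"
MODE_LIST_VS_GENOME = "LIST_VS_GENOME"


@dataclass(frozen=True)
class EnrichmentRecord:
    """One (cluster, annotation) enrichment test.

    The 2x2 table is: ``a`` carriers among the ``n`` cluster (or list) genes
    versus ``K_list`` carriers among the ``N`` list (or genome) genes.
    """

    level_k: int
    cluster_index: int
    cluster_size: int
    system_label: str
    annotation: str
    mode: str
    background: str
    a: int
    K_list: int
    n: int
    N: int
    p_raw: float
    p_fdr: float

    def __post_init__(self):
        _check_counts(self.a, self.n, self.K_list, self.N)
        if not 0.0 < self.p_raw <= 1.0:
            raise ValueError("p_raw must lie in (0, 1]")
        if not self.p_raw <= self.p_fdr <= 1.0 + 1e-12:
            raise ValueError("p_fdr must lie in [p_raw, 1]")


@dataclass(frozen=True)
class InterCorrelationRecord:
    """Fisher association between a cluster from each of two trees."""

    level_a: int
    cluster_a: int
    size_a: int
    level_b: int
    cluster_b: int
    size_b: int
    overlap: int
    universe_size: int
    p_raw: float
    p_fdr: float

    def __post_init__(self):
        if self.overlap > min(self.size_a, self.size_b):
            raise ValueError("overlap cannot exceed either cluster size")
        if self.p_fdr < self.p_raw - 1e-12:
            raise ValueError("p_fdr must be >= p_raw")


def _check_counts(a: int, n: int, K: int, N: int) -> None:
    if not (0 <= a <= min(n, K) and 0 < n <= N and 0 <= K <= N):
        raise ValueError(
            f"invalid 2x2 counts: a={a}, n={n}, K={K}, N={N} "
            f"(need 0 <= a <= min(n, K), 0 < n <= N, K <= N)"
        )
    if a < n + K - N:
        raise ValueError(
            f"invalid 2x2 counts: a={a} below support minimum {n + K - N}"
        )


def fisher_enrichment_p(a: int, n: int, K_list: int, N: int) -> float:
    """One-sided over-representation p-value, P(X >= a).

    X follows the hypergeometric distribution of drawing ``n`` genes without
    replacement from a population of ``N`` containing ``K_list`` carriers.
    """
    _check_counts(a, n, K_list, N)
    return float(np.clip(hypergeom.sf(a - 1, N, K_list, n), 0.0, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=np.float64)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _records_with_fdr(raw_records: list[dict]) -> list[EnrichmentRecord]:
    if not raw_records:
        return []
    adjusted = bh_fdr([r["p_raw"] for r in raw_records])
    return [
        EnrichmentRecord(p_fdr=float(q), **r) for r, q in zip(raw_records, adjusted)
    ]


def enrich_clusters(
    level: ClusteringLevel,
    test_matrix: AnnotationMatrix,
    gene_list: GeneList,
    mode: str,
    fdr_family: str = "level",
) -> list[EnrichmentRecord]:
    """Test every (nonempty cluster, occurring annotation) pair vs the list.

    For each nonempty cluster and each annotation with at least one carrier
    in that cluster, the cluster's carriers ``a`` of ``n`` genes are tested
    against the list's carriers ``K_list`` of ``N`` genes. ``N`` is the full
    input list size: list genes without any annotation in the tested system
    count as non-carriers. ``mode`` is ``"IEA"`` when ``test_matrix`` comes
    from the other annotation system than the one clustered, ``"DEA"``
    otherwise; DEA values are descriptive scores, not tests.

    ``fdr_family`` is ``"level"`` (default; BH across all tests of this
    call) or ``"cluster"`` (BH separately within each cluster).
    """
    if mode not in (MODE_DEA, MODE_IEA):
        raise ValueError(f"mode must be DEA or IEA, got {mode!r}")
    if fdr_family not in ("level", "cluster"):
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    list_members = set(gene_list.members)
    outside = [g for g in level.assignment if g not in list_members]
    if outside:
        raise ValueError(f"cluster genes absent from the gene list: {outside[:5]}")
    N = len(gene_list)
    carriers_by_annotation = {
        ann: test_matrix.carriers(ann) & list_members
        for ann in test_matrix.annotations
    }
    families: list[list[dict]] = []
    current: list[dict] = []
    for cluster in level.nonempty_clusters():
        members = level.members(cluster)
        n = len(members)
        cluster_rows: list[dict] = []
        for ann in test_matrix.annotations:
            carriers = carriers_by_annotation[ann]
            a = len(members & carriers)
            if a == 0:
                continue  # only annotations occurring in the cluster are tested
            K = len(carriers)
            cluster_rows.append(
                dict(
                    level_k=level.k_requested,
                    cluster_index=cluster,
                    cluster_size=n,
                    system_label=test_matrix.system_label,
                    annotation=ann,
                    mode=mode,
                    background="list",
                    a=a,
                    K_list=K,
                    n=n,
                    N=N,
                    p_raw=fisher_enrichment_p(a, n, K, N),
                )
            )
        if fdr_family == "cluster":
            families.append(cluster_rows)
        else:
            current.extend(cluster_rows)
    if fdr_family == "level":
        families = [current]
    records: list[EnrichmentRecord] = []
    for family in families:
        records.extend(_records_with_fdr(family))
    return records


def enrich_list_vs_genome(
    gene_list: GeneList, genome_matrix: AnnotationMatrix, fdr_family: str = "batch"
) -> list[EnrichmentRecord]:
    """Classical over-representation of the list against a genome background.

    List genes absent from the genome matrix are logged and dropped from the
    test (they cannot be scored against the background). Supplies the
    "List p-value" evidence attached to level-1 of a tree.
    """
    import logging

    logger = logging.getLogger(__name__)
    genome_genes = set(genome_matrix.genes)
    effective = [g for g in gene_list if g in genome_genes]
    dropped = [g for g in gene_list if g not in genome_genes]
    if dropped:
        logger.info(
            "list vs genome: dropped %d list genes absent from the genome "
            "background", len(dropped)
        )
    if not effective:
        raise ValueError("no list genes present in the genome background")
    N = genome_matrix.n_genes
    n = len(effective)
    effective_set = set(effective)
    rows: list[dict] = []
    for j, ann in enumerate(genome_matrix.annotations):
        carriers = genome_matrix.carriers(ann)
        a = len(effective_set & carriers)
        if a == 0:
            continue
        K = len(carriers)
        rows.append(
            dict(
                level_k=1,
                cluster_index=0,
                cluster_size=n,
                system_label=genome_matrix.system_label,
                annotation=ann,
                mode=MODE_LIST_VS_GENOME,
                background="genome",
                a=a,
                K_list=K,
                n=n,
                N=N,
                p_raw=fisher_enrichment_p(a, n, K, N),
            )
        )
    return _records_with_fdr(rows)


def inter_correlation(
    level_a: ClusteringLevel,
    level_b: ClusteringLevel,
    universe=None,
) -> list[InterCorrelationRecord]:
    """Fisher association for every cluster pair across two trees.

    For clusters A (one tree) and B (the other) over the shared universe U,
    the one-sided Fisher test is applied to the overlap table
    ``[|A&B|, |A\\B|; |B\\A|, |U\\(A|B)|]``; BH correction runs across all
    pairs of the comparison. The default universe is the set of genes
    clustered in BOTH trees; the correction is known to be conservative here
    because the pairs share genes.
    """
    if universe is None:
        universe = set(level_a.assignment) & set(level_b.assignment)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    N = len(universe)
    rows = []
    raw = []
    for ca in level_a.nonempty_clusters():
        members_a = level_a.members(ca) & universe
        if not members_a:
            continue
        for cb in level_b.nonempty_clusters():
            members_b = level_b.members(cb) & universe
            if not members_b:
                continue
            overlap = len(members_a & members_b)
            p = fisher_enrichment_p(overlap, len(members_a), len(members_b), N)
            rows.append(
                dict(
                    level_a=level_a.k_requested,
                    cluster_a=ca,
                    size_a=len(members_a),
                    level_b=level_b.k_requested,
                    cluster_b=cb,
                    size_b=len(members_b),
                    overlap=overlap,
                    universe_size=N,
                )
            )
            raw.append(p)
    if not rows:
        return []
    adjusted = bh_fdr(raw)
    records = [
        InterCorrelationRecord(p_raw=p, p_fdr=float(q), **row)
        for row, p, q in zip(rows, raw, adjusted)
    ]
    records.sort(
        key=lambda r: (r.p_fdr, r.p_raw, r.level_a, r.cluster_a, r.cluster_b)
    )
    return records
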