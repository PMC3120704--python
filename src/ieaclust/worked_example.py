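"""Published worked-example contingency tables for cross-annotation enrichment.

These rows reproduce the independent-enrichment results reported for three
differential-expression gene lists: forskolin-treated HEK293T cells (691 DE
genes) and the up- and down-regulated genes of ruptured vs unruptured
intracranial aneurysm walls (498 and 491 DE genes). Each row fixes a full
2x2 table: ``a`` annotation carriers inside a cluster of ``n`` genes versus
``K`` carriers in the whole list of ``N`` genes. The published p-values are
FDR-corrected, so the raw one-sided Fisher tail computed from the counts
must not exceed them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .enrichment import fisher_enrichment_p


@dataclass(frozen=True)
class WorkedExampleRow:
    key: str
    dataset: str
    annotation: str
    a: int  # carriers in the cluster
    n: int  # cluster size
    K: int  # carriers in the DE list
    N: int  # DE list size
    published_fdr_p: float

    def raw_p(self) -> float:
        return fisher_enrichment_p(self.a, self.n, self.K, self.N)


WORKED_EXAMPLE_ROWS: tuple[WorkedExampleRow, ...] = (
    # forskolin list (691 genes): TFs enriched in GO-derived clusters
    WorkedExampleRow("forskolin_cluster26_hes1_raw_p", "forskolin", "HES-1",
                     8, 26, 32, 691, 2.0e-2),
    WorkedExampleRow("forskolin_cluster26_ahr_raw_p", "forskolin", "AhR",
                     15, 26, 123, 691, 2.9e-2),
    WorkedExampleRow("forskolin_cluster50_foxo1_raw_p", "forskolin", "FOXO1",
                     10, 50, 32, 691, 3.3e-2),
    # forskolin: GO term enriched in a TF-derived cluster
    WorkedExampleRow("forskolin_tf33_organelle_organization_raw_p", "forskolin",
                     "organelle organization", 12, 33, 50, 691, 2.5e-3),
    # aneurysm up-regulated list (498 genes)
    WorkedExampleRow("aneurysm_up_mtf1_raw_p", "aneurysm_up", "MTF-1",
                     13, 58, 30, 498, 4.8e-2),
    WorkedExampleRow("aneurysm_up_atf1_raw_p", "aneurysm_up", "ATF-1",
                     9, 58, 17, 498, 4.8e-2),
    WorkedExampleRow("aneurysm_up_amine_biosynthesis_raw_p", "aneurysm_up",
                     "amine biosynthetic process", 3, 29, 4, 498, 9.1e-2),
    # aneurysm down-regulated list (491 genes)
    WorkedExampleRow("aneurysm_down_tal1_raw_p", "aneurysm_down", "Tal-1",
                     4, 22, 5, 491, 3.1e-2),
    WorkedExampleRow("aneurysm_down_ar_raw_p", "aneurysm_down", "AR",
                     6, 22, 17, 491, 9.4e-2),
    WorkedExampleRow("aneurysm_down_nf1_raw_p", "aneurysm_down", "NF-1",
                     14, 49, 30, 491, 3.7e-2),
)
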