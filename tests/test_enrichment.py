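import math

import numpy as np
import pytest

from ieaclust import (
    GeneList,
    bh_fdr,
    enrich_clusters,
    enrich_list_vs_genome,
    fisher_enrichment_p,
    inter_correlation,
)
from ieaclust.clustering import ClusteringLevel
from ieaclust.io import AnnotationMatrix


def hypergeom_tail_oracle(a, n, K, N):
    """Exact tail P(X >= a) by direct enumeration with integer binomials."""
    total = math.comb(N, n)
    acc = 0
    for x in range(a, min(n, K) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


class TestFisherEnrichmentP:
    def test_zero_overlap_is_certain(self):
        assert fisher_enrichment_p(0, 10, 5, 100) == 1.0

    def test_full_containment_closed_form(self):
        # drawing all 5 carriers in 5 draws from 10: 1 / C(10,5)
        assert fisher_enrichment_p(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_worked_example_tail_below_printed_fdr_value(self):
        # 8 carriers in a 26-gene cluster vs 32 carriers in a 691-gene list;
        # the printed FDR-corrected value 2.0e-2 upper-bounds the raw tail
        assert fisher_enrichment_p(8, 26, 32, 691) <= 2.0e-2

    def test_invalid_counts_error(self):
        for bad in [(6, 5, 10, 100), (3, 5, 2, 100), (1, 5, 10, 8)]:
            with pytest.raises(ValueError):
                fisher_enrichment_p(*bad)

    def test_matches_enumeration_oracle_on_small_populations(self):
        for N in (8, 13, 21):
            for n in range(1, N + 1, 3):
                for K in range(0, N + 1, 2):
                    for a in range(max(0, n + K - N), min(n, K) + 1):
                        expected = hypergeom_tail_oracle(a, n, K, N)
                        got = fisher_enrichment_p(a, n, K, N)
                        assert got == pytest.approx(expected, rel=1e-10)


def bh_stepup_oracle(p):
    """Independent BH implementation: literal min over j >= i of p(j)*m/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank, i in enumerate(order, start=1):
        adj[i] = min(
            min(1.0, p[j] * m / (sorted_rank))
            for sorted_rank, j in enumerate(order, start=1)
            if sorted_rank >= rank
        )
    return adj


class TestBhFdr:
    def test_single_value_unchanged(self):
        assert bh_fdr([0.04]).tolist() == [0.04]

    def test_equal_values_are_fixed_point(self):
        out = bh_fdr([0.3] * 7)
        assert np.allclose(out, 0.3)

    def test_step_up_example(self):
        out = bh_fdr([0.01, 0.04, 0.03, 0.02])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_errors(self):
        for bad in ([0.0, 0.5], [0.5, 1.5]):
            with pytest.raises(ValueError):
                bh_fdr(bad)

    def test_matches_independent_stepup_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            p = rng.random(rng.integers(1, 25)).clip(1e-9, 1.0)
            assert np.allclose(bh_fdr(p), bh_stepup_oracle(list(p)))

    def test_adjusted_at_least_raw_and_order_preserving(self):
        rng = np.random.default_rng(1)
        p = rng.random(40).clip(1e-9, 1)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def _matrix_from_sets(genes, sets, label="TF"):
    annots = tuple(sets)
    inc = np.zeros((len(genes), len(annots)), dtype=np.int8)
    for j, ann in enumerate(annots):
        for g in sets[ann]:
            inc[genes.index(g), j] = 1
    return AnnotationMatrix(label, tuple(genes), annots, inc)


class TestEnrichClusters:
    def _setup(self):
        genes = [f"g{i}" for i in range(12)]
        gl = GeneList(tuple(genes))
        level = ClusteringLevel(
            2,
            {g: (0 if i < 6 else 1) for i, g in enumerate(genes)},
            0.0,
            seed=0,
            n_restarts_used=1,
        )
        tf = _matrix_from_sets(
            genes,
            {
                "T_in_c0": ["g0", "g1", "g2", "g3"],
                "T_everywhere": genes[:3] + genes[6:9],
                "T_only_c1": ["g7", "g8"],
                "T_all": genes,
            },
        )
        return gl, level, tf

    def test_absent_annotation_produces_no_record(self):
        gl, level, tf = self._setup()
        records = enrich_clusters(level, tf, gl, mode="IEA")
        keys = {(r.cluster_index, r.annotation) for r in records}
        assert ("T_only_c1" not in {a for c, a in keys if c == 0})
        assert (0, "T_in_c0") in keys

    def test_counts_and_background_are_list_wide(self):
        gl, level, tf = self._setup()
        records = enrich_clusters(level, tf, gl, mode="IEA")
        r = next(
            r for r in records if r.cluster_index == 0 and r.annotation == "T_in_c0"
        )
        assert (r.a, r.n, r.K_list, r.N) == (4, 6, 4, 12)
        assert r.p_raw == pytest.approx(fisher_enrichment_p(4, 6, 4, 12))
        assert r.mode == "IEA"

    def test_cluster_genes_outside_list_error(self):
        gl, level, tf = self._setup()
        bad = ClusteringLevel(1, {"nope": 0}, 0.0, seed=0, n_restarts_used=1)
        with pytest.raises(ValueError, match="absent from the gene list"):
            enrich_clusters(bad, tf, gl, mode="DEA")

    def test_fdr_family_within_level_covers_all_records(self):
        gl, level, tf = self._setup()
        records = enrich_clusters(level, tf, gl, mode="IEA", fdr_family="level")
        raws = [r.p_raw for r in records]
        adj = bh_fdr(raws)
        for r, q in zip(records, adj):
            assert r.p_fdr == pytest.approx(float(q))

    def test_p_equal_one_records_retained(self):
        gl, level, tf = self._setup()
        records = enrich_clusters(level, tf, gl, mode="DEA")
        assert any(r.p_raw == 1.0 for r in records)


class TestEnrichListVsGenome:
    def test_list_equal_to_genome_gives_p_one(self):
        genes = [f"g{i}" for i in range(8)]
        genome = _matrix_from_sets(genes, {"A": genes[:5]}, label="GO")
        records = enrich_list_vs_genome(GeneList(tuple(genes)), genome)
        assert all(r.p_raw == 1.0 for r in records)

    def test_concentrated_annotation_matches_enumeration_oracle(self):
        genes = [f"g{i}" for i in range(100)]
        carriers = genes[:10]
        genome = _matrix_from_sets(genes, {"Z": carriers}, label="GO")
        records = enrich_list_vs_genome(GeneList(tuple(carriers)), genome)
        [r] = records
        assert r.p_raw == pytest.approx(
            hypergeom_tail_oracle(10, 10, 10, 100), rel=1e-10
        )

    def test_zero_occurrence_annotations_excluded(self):
        genes = [f"g{i}" for i in range(10)]
        genome = _matrix_from_sets(
            genes, {"A": genes[:4], "B": genes[5:]}, label="GO"
        )
        records = enrich_list_vs_genome(GeneList(tuple(genes[:4])), genome)
        assert {r.annotation for r in records} == {"A"}

    def test_disjoint_list_errors(self):
        genes = [f"g{i}" for i in range(6)]
        genome = _matrix_from_sets(genes, {"A": genes[:3]}, label="GO")
        with pytest.raises(ValueError, match="no list genes"):
            enrich_list_vs_genome(GeneList(("x", "y")), genome)


def _level_from_labels(k, labels, genes):
    return ClusteringLevel(
        k, {g: int(c) for g, c in zip(genes, labels)}, 0.0, seed=0, n_restarts_used=1
    )


class TestInterCorrelation:
    def test_identical_partitions_self_pairs_minimal(self):
        genes = [f"g{i}" for i in range(20)]
        labels = [i // 5 for i in range(20)]
        la = _level_from_labels(4, labels, genes)
        lb = _level_from_labels(4, labels, genes)
        records = inter_correlation(la, lb)
        for ca in range(4):
            row = [r for r in records if r.cluster_a == ca]
            best = min(row, key=lambda r: r.p_raw)
            assert best.cluster_b == ca
            assert best.overlap == 5

    def test_equal_five_sets_over_twenty_closed_form(self):
        genes = [f"g{i}" for i in range(20)]
        la = _level_from_labels(2, [0] * 5 + [1] * 15, genes)
        lb = _level_from_labels(2, [0] * 5 + [1] * 15, genes)
        records = inter_correlation(la, lb)
        r = next(r for r in records if r.cluster_a == 0 and r.cluster_b == 0)
        assert r.p_raw == pytest.approx(1 / math.comb(20, 5), rel=1e-10)

    def test_empty_universe_errors(self):
        la = _level_from_labels(1, [0], ["g1"])
        lb = _level_from_labels(1, [0], ["g2"])
        with pytest.raises(ValueError, match="empty universe"):
            inter_correlation(la, lb)

    def test_null_partitions_rarely_called_significant(self):
        """Independent random partitions: after BH the mean fraction of pairs
        at FDR < 0.05 stays at the nominal level (the correction is in fact
        conservative here because pairs share genes)."""
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(60)]
        fractions = []
        for _ in range(50):
            la = _level_from_labels(3, rng.permutation(np.arange(60) % 3), genes)
            lb = _level_from_labels(4, rng.permutation(np.arange(60) % 4), genes)
            records = inter_correlation(la, lb)
            fractions.append(
                sum(r.p_fdr < 0.05 for r in records) / len(records)
            )
        assert np.mean(fractions) <= 0.06

    def test_records_sorted_by_adjusted_p(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(30)]
        la = _level_from_labels(3, rng.integers(0, 3, 30), genes)
        lb = _level_from_labels(4, rng.integers(0, 4, 30), genes)
        records = inter_correlation(la, lb)
        assert len(records) == len(la.nonempty_clusters()) * len(lb.nonempty_clusters())
        fdrs = [r.p_fdr for r in records]
        assert fdrs == sorted(fdrs)
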