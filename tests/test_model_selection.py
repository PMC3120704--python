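import math

import numpy as np
import pytest

from ieaclust import (
    aic_level,
    aic_per_dimension,
    bernoulli_loglik,
    build_levels,
    daic_dimension_filter,
    daic_scores,
    select_best_level,
)
from ieaclust.io import AnnotationMatrix
from ieaclust.model_selection import ModelScore


def _matrix(incidence, label="GO"):
    incidence = np.asarray(incidence, dtype=np.int8)
    genes = tuple(f"g{i}" for i in range(incidence.shape[0]))
    annots = tuple(f"a{j}" for j in range(incidence.shape[1]))
    return AnnotationMatrix(label, genes, annots, incidence)


def _one_cluster(matrix):
    return {g: 0 for g in matrix.genes}


class TestBernoulliLoglik:
    def test_degenerate_rate_contributes_zero(self):
        m = _matrix([[1], [1]])
        assert bernoulli_loglik(m, _one_cluster(m)) == 0.0

    def test_half_rate_closed_form(self):
        m = _matrix([[1], [0]])
        assert bernoulli_loglik(m, _one_cluster(m)) == pytest.approx(2 * math.log(0.5))

    def test_matches_cell_by_cell_oracle_on_random_matrix(self):
        rng = np.random.default_rng(5)
        inc = (rng.random((6, 3)) < 0.5).astype(int)
        m = _matrix(inc)
        assignment = {g: (0 if i < 3 else 1) for i, g in enumerate(m.genes)}
        # independent oracle: literal sum of ln theta / ln(1-theta) per cell
        expected = 0.0
        for c in (0, 1):
            rows = [i for i, g in enumerate(m.genes) if assignment[g] == c]
            for j in range(3):
                ones = sum(inc[i, j] for i in rows)
                theta = ones / len(rows)
                for i in rows:
                    if inc[i, j]:
                        expected += math.log(theta) if theta > 0 else 0.0
                    else:
                        expected += math.log(1 - theta) if theta < 1 else 0.0
        assert bernoulli_loglik(m, assignment) == pytest.approx(expected)

    def test_empty_dimension_subset_errors(self):
        m = _matrix([[1], [0]])
        with pytest.raises(ValueError, match="empty dimension"):
            bernoulli_loglik(m, _one_cluster(m), dimensions=[])

    def test_loglik_non_decreasing_under_refinement(self):
        rng = np.random.default_rng(9)
        inc = (rng.random((8, 4)) < 0.4).astype(int)
        m = _matrix(inc)
        coarse = {g: (0 if i < 4 else 1) for i, g in enumerate(m.genes)}
        refined = {g: i // 2 for i, g in enumerate(m.genes)}  # splits both halves
        assert bernoulli_loglik(m, refined) >= bernoulli_loglik(m, coarse) - 1e-12


class TestAicLevel:
    def test_all_zero_dimensions_aic_is_parameter_cost_only(self):
        m = _matrix(np.zeros((5, 3), dtype=int))
        score = aic_level(m, _one_cluster(m))
        assert score.log_likelihood == 0.0
        assert score.aic == 6.0

    def test_single_half_column_closed_form(self):
        m = _matrix([[1], [0]])
        score = aic_level(m, _one_cluster(m))
        assert score.aic == pytest.approx(2 - 4 * math.log(0.5))

    def test_true_partition_beats_one_cluster_on_blocks(
        self, two_block_matrix, two_block_partition
    ):
        aic_k2 = aic_level(two_block_matrix, two_block_partition).aic
        aic_k1 = aic_level(two_block_matrix, _one_cluster(two_block_matrix)).aic
        assert aic_k2 < aic_k1

    def test_aic_identity_holds(self, two_block_matrix, two_block_partition):
        s = aic_level(two_block_matrix, two_block_partition)
        assert s.aic == pytest.approx(2 * s.n_parameters - 2 * s.log_likelihood)

    def test_parameters_counted_for_nonempty_clusters_only(self):
        m = _matrix([[1], [0]])
        sparse = {"g0": 0, "g1": 3}  # indices 1 and 2 empty
        score = aic_level(m, sparse, level_k=4)
        assert score.n_parameters == 2


class TestAicPerDimension:
    @pytest.mark.parametrize("k,expected", [(1, 2.0), (3, 6.0)])
    def test_all_zero_column_cost(self, k, expected):
        m = _matrix(np.zeros((6, 1), dtype=int))
        assignment = {g: i % k for i, g in enumerate(m.genes)}
        assert aic_per_dimension(m, assignment, "a0") == pytest.approx(expected)

    def test_perfectly_split_column_improves_on_k1(self):
        m = _matrix([[1], [1], [1], [0], [0], [0]])
        one = _one_cluster(m)
        split = {g: (0 if i < 3 else 1) for i, g in enumerate(m.genes)}
        aic1 = aic_per_dimension(m, one, "a0")
        aic2 = aic_per_dimension(m, split, "a0")
        assert aic2 == pytest.approx(4.0)
        assert aic1 == pytest.approx(2 - 2 * 6 * math.log(0.5))
        assert aic2 < aic1


class TestDaicFilter:
    def test_all_zero_column_never_retained(self):
        inc = np.zeros((12, 2), dtype=int)
        inc[:6, 1] = 1  # informative column so clustering input is valid
        m = _matrix(inc)
        levels = build_levels(m, 4, seed=0, restarts=2)
        retained = daic_dimension_filter(m, levels)
        assert "a0" not in retained

    def test_cluster_aligned_column_retained(self, two_block_matrix):
        levels = build_levels(two_block_matrix, 4, seed=0, restarts=4)
        retained = daic_dimension_filter(two_block_matrix, levels, min_k_filter=2)
        # with perfect 5x3 blocks every signal column aligns with the partition
        assert retained == frozenset(two_block_matrix.annotations)

    def test_requires_k1_level(self, two_block_matrix):
        levels = build_levels(two_block_matrix, 3, seed=0, restarts=2)[1:]
        with pytest.raises(ValueError, match="k=1"):
            daic_dimension_filter(two_block_matrix, levels)


class TestDaicScores:
    def test_all_dimensions_retained_equals_aic(self, two_block_matrix):
        levels = build_levels(two_block_matrix, 3, seed=0, restarts=3)
        scores = daic_scores(
            two_block_matrix, levels, frozenset(two_block_matrix.annotations)
        )
        for lv, s in zip(levels, scores):
            plain = aic_level(two_block_matrix, lv.assignment, level_k=lv.k_requested)
            assert s.daic == pytest.approx(plain.aic)

    def test_empty_retained_set_errors(self, two_block_matrix):
        levels = build_levels(two_block_matrix, 2, seed=0, restarts=2)
        with pytest.raises(ValueError, match="empty retained"):
            daic_scores(two_block_matrix, levels, frozenset())


class TestSelectBestLevel:
    def _scores(self, values):
        return [
            ModelScore(k, -v / 2, 0, v, daic=v)
            for k, v in enumerate(values, start=1)
        ]

    def test_minimum_selected(self):
        assert select_best_level(self._scores([10, 5, 7])) == 2

    def test_tie_prefers_smaller_k(self):
        assert select_best_level(self._scores([5, 5])) == 1

    def test_single_level(self):
        assert select_best_level(self._scores([3])) == 1
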