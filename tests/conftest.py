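import numpy as np
import pytest

from ieaclust.io import AnnotationMatrix, GeneList


@pytest.fixture
def two_block_matrix() -> AnnotationMatrix:
    """10 genes x 6 annotations: two perfect disjoint 5x3 blocks."""
    genes = tuple(f"g{i}" for i in range(10))
    annotations = tuple(f"a{j}" for j in range(6))
    incidence = np.zeros((10, 6), dtype=np.int8)
    incidence[:5, :3] = 1
    incidence[5:, 3:] = 1
    return AnnotationMatrix("GO", genes, annotations, incidence)


@pytest.fixture
def two_block_partition(two_block_matrix) -> dict:
    return {g: 0 if i < 5 else 1 for i, g in enumerate(two_block_matrix.genes)}


@pytest.fixture
def small_list() -> GeneList:
    return GeneList(tuple(f"g{i}" for i in range(10)))
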