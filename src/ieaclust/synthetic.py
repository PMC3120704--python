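"""Planted-partition generator for paired binary annotation systems.

Emulates the input of a cross-annotation analysis: a gene list annotated in
two systems (a "GO"-like and a "TF"-like one) whose annotations carry a
common latent cluster structure. Each of the ``k_true`` planted clusters
owns ``signal_dims`` disjoint annotation columns per system; a gene carries
its own cluster's signal annotations with probability ``p_in`` and any other
signal or background annotation with probability ``p_out``. The second
system follows the same planted partition with probability ``coupling``
(drawn once per dataset), else an independent random partition of identical
cluster sizes — giving a clean alternative (coupled) vs null (uncoupled)
dichotomy for power and type-I-error evaluation of independent enrichment
analysis.

The generator produces idealized data: disjoint signal columns, i.i.d.
noise, equal-prevalence clusters. Real GO/TF annotations are hierarchical,
overlapping and biased toward well-studied genes, so recovery rates measured
here bound what structure of this strength would give, not what any
particular real dataset gives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .io import AnnotationMatrix, GeneList


@dataclass(frozen=True)
class SyntheticParams:
    """Generator parameters; defaults are the package's standard test regime."""

    n_genes: int = 200
    k_true: int = 4
    signal_dims: int = 3
    background_dims: int = 20
    p_in: float = 0.9
    p_out: float = 0.05
    coupling: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.k_true <= self.n_genes:
            raise ValueError("need n_genes >= k_true >= 1")
        if self.signal_dims < 1 or self.background_dims < 0:
            raise ValueError("signal_dims >= 1 and background_dims >= 0 required")
        for name in ("p_in", "p_out", "coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SyntheticDataset:
    """Two coupled annotation matrices plus the ground-truth partition."""

    params: SyntheticParams
    partition: dict[str, int]
    partition_two: dict[str, int]
    system_one: AnnotationMatrix
    system_two: AnnotationMatrix
    coupled: bool

    @property
    def gene_list(self) -> GeneList:
        return GeneList(self.system_one.genes)

    def signal_annotations(self, system: int, cluster: int) -> list[str]:
        """The annotation columns planted for ``cluster`` in one system."""
        prefix = f"S{system}_c{cluster}_sig"
        matrix = self.system_one if system == 1 else self.system_two
        return [a for a in matrix.annotations if a.startswith(prefix)]


def _plant_matrix(
    rng: np.random.Generator,
    labels: np.ndarray,
    params: SyntheticParams,
    system: int,
) -> tuple[list[str], np.ndarray]:
    k, s, b = params.k_true, params.signal_dims, params.background_dims
    n = params.n_genes
    names = [
        f"S{system}_c{c}_sig{d}" for c in range(k) for d in range(s)
    ] + [f"S{system}_bg{d}" for d in range(b)]
    col_cluster = np.repeat(np.arange(k), s)  # owning cluster of signal cols
    prob = np.full((n, k * s + b), params.p_out)
    own = labels[:, None] == col_cluster[None, :]
    prob[:, : k * s][own] = params.p_in
    incidence = (rng.random(prob.shape) < prob).astype(np.int8)
    return names, incidence


def generate(params: SyntheticParams) -> SyntheticDataset:
    """Draw one dataset; a fixed seed yields byte-identical output."""
    rng = np.random.default_rng(params.seed)
    n, k = params.n_genes, params.k_true
    genes = tuple(f"g{i:04d}" for i in range(n))
    # balanced planted partition (sizes differ by at most one)
    labels_one = np.sort(np.arange(n) % k)
    coupled = bool(rng.random() < params.coupling)
    if coupled:
        labels_two = labels_one.copy()
    else:
        labels_two = rng.permutation(labels_one)
    names_one, inc_one = _plant_matrix(rng, labels_one, params, system=1)
    names_two, inc_two = _plant_matrix(rng, labels_two, params, system=2)
    return SyntheticDataset(
        params=params,
        partition={g: int(c) for g, c in zip(genes, labels_one)},
        partition_two={g: int(c) for g, c in zip(genes, labels_two)},
        system_one=AnnotationMatrix("S1", genes, tuple(names_one), inc_one),
        system_two=AnnotationMatrix("S2", genes, tuple(names_two), inc_two),
        coupled=coupled,
    )


def adjusted_rand_index(partition_a: dict[str, int], partition_b: dict[str, int]) -> float:
    """Chance-corrected Rand agreement between two partitions of one gene set."""
    if set(partition_a) != set(partition_b):
        raise ValueError("partitions cover different gene sets")
    genes = sorted(partition_a)
    la = [partition_a[g] for g in genes]
    lb = [partition_b[g] for g in genes]
    return float(adjusted_rand_score(la, lb))


def write_dataset(dataset: SyntheticDataset, out_dir, fmt: str = "pairs") -> dict[str, str]:
    """Emit a dataset as pipeline input files (gene list + two systems).

    ``fmt`` is ``"pairs"`` (two-column TSV) or ``"gmt"``. Returns the paths
    written, keyed ``genes``/``system_one``/``system_two``.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"genes": str(out_dir / "genes.txt")}
    with open(paths["genes"], "w", encoding="utf-8") as fh:
        for g in dataset.system_one.genes:
            fh.write(g + "\n")
    for key, matrix in (("system_one", dataset.system_one), ("system_two", dataset.system_two)):
        if fmt == "pairs":
            path = out_dir / f"{key}.tsv"
            with open(path, "w", encoding="utf-8") as fh:
                for i, g in enumerate(matrix.genes):
                    for j in np.flatnonzero(matrix.incidence[i]):
                        fh.write(f"{g}\t{matrix.annotations[j]}\n")
        elif fmt == "gmt":
            path = out_dir / f"{key}.gmt"
            with open(path, "w", encoding="utf-8") as fh:
                for j, ann in enumerate(matrix.annotations):
                    members = [
                        matrix.genes[i] for i in np.flatnonzero(matrix.incidence[:, j])
                    ]
                    if members:
                        fh.write("\t".join([ann, "synthetic"] + members) + "\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")
        paths[key] = str(path)
    return paths
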