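"""Readers and writers for gene lists, annotation matrices and result tables.

Input formats are deliberately plain: one-identifier-per-line gene lists,
two-column ``gene<TAB>annotation`` association files, and GMT gene-set files.
Gene identifiers are opaque, case-sensitive strings; no symbol/ID mapping or
ontology-ancestor expansion is performed here — associations are used exactly
as given.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "level",
    "cluster",
    "cluster_size",
    "system",
    "annotation",
    "mode",
    "background",
    "count_in_cluster",
    "count_in_list",
    "list_size",
    "p_raw",
    "p_fdr",
]


class ParseError(ValueError):
    """A malformed line in an input file."""


@dataclass(frozen=True)
class GeneList:
    """An ordered, duplicate-free list of gene identifiers."""

    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError("empty gene list")
        if len(set(self.members)) != len(self.members):
            raise ValueError("gene list contains duplicates")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)


@dataclass
class AnnotationMatrix:
    """Binary gene x annotation incidence for one annotation system.

    Rows are genes, columns are annotations; a cell value of one indicates
    that the gene carries the annotation, zero that it does not.

    Parameters
    ----------
    system_label
        Name of the annotation system (e.g. ``"GO"`` or ``"TF"``).
    genes, annotations
        Ordered, duplicate-free identifier lists for rows and columns.
    incidence
        Array of shape ``(len(genes), len(annotations))`` with values in
        ``{0, 1}``.
    """

    system_label: str
    genes: tuple[str, ...]
    annotations: tuple[str, ...]
    incidence: np.ndarray

    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.genes = tuple(self.genes)
        self.annotations = tuple(self.annotations)
        self.incidence = np.asarray(self.incidence, dtype=np.int8)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.annotations)) != len(self.annotations):
            raise ValueError("duplicate annotation identifiers")
        if self.incidence.shape != (len(self.genes), len(self.annotations)):
            raise ValueError(
                f"incidence shape {self.incidence.shape} does not match "
                f"({len(self.genes)}, {len(self.annotations)})"
            )
        if not np.isin(self.incidence, (0, 1)).all():
            raise ValueError("incidence values must be 0 or 1")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_annotations(self) -> int:
        return len(self.annotations)

    def gene_row(self, gene: str) -> np.ndarray:
        return self.incidence[self._gene_index[gene]]

    def carriers(self, annotation: str) -> set[str]:
        """Genes annotated with ``annotation``."""
        j = self.annotations.index(annotation)
        return {self.genes[i] for i in np.flatnonzero(self.incidence[:, j])}


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_gene_list(path) -> GeneList:
    """Read a one-identifier-per-line gene list.

    Blank lines and lines starting with ``#`` are ignored; surrounding
    whitespace is trimmed; duplicates are collapsed keeping the first
    occurrence (with a logged warning); order is otherwise preserved.
    """
    path = Path(path)
    seen: dict[str, None] = {}
    n_dupes = 0
    for _, line in _data_lines(path):
        ident = line.strip()
        if ident in seen:
            n_dupes += 1
        else:
            seen[ident] = None
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate gene identifiers", path, n_dupes)
    if not seen:
        raise ValueError(f"{path}: empty gene list")
    return GeneList(tuple(seen))


def _matrix_from_pairs(
    pairs: Iterable[tuple[str, str]], system_label: str
) -> AnnotationMatrix:
    genes: dict[str, None] = {}
    annots: dict[str, None] = {}
    uniq = set()
    pair_list = []
    for g, a in pairs:
        genes.setdefault(g, None)
        annots.setdefault(a, None)
        if (g, a) not in uniq:
            uniq.add((g, a))
            pair_list.append((g, a))
    gene_idx = {g: i for i, g in enumerate(genes)}
    annot_idx = {a: j for j, a in enumerate(annots)}
    incidence = np.zeros((len(genes), len(annots)), dtype=np.int8)
    for g, a in pair_list:
        incidence[gene_idx[g], annot_idx[a]] = 1
    return AnnotationMatrix(system_label, tuple(genes), tuple(annots), incidence)


def read_pairs_tsv(path, system_label: str) -> AnnotationMatrix:
    """Read a two-column ``gene<TAB>annotation`` association file.

    Repeated pairs set the incidence cell to one exactly once. Blank and
    ``#`` comment lines are skipped.
    """
    path = Path(path)
    pairs = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise ValueError(f"{path}: no associations found")
    return _matrix_from_pairs(pairs, system_label)


def read_gmt(path, system_label: str) -> AnnotationMatrix:
    """Read a GMT gene-set file: ``setname<TAB>description<TAB>gene1<TAB>...``.

    Each set becomes one annotation column; member genes get incidence one.
    """
    path = Path(path)
    pairs = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line needs set name, description and "
                f"at least one gene (got {len(fields)} fields)"
            )
        set_name = fields[0].strip()
        for g in fields[2:]:
            g = g.strip()
            if g:
                pairs.append((g, set_name))
    if not pairs:
        raise ValueError(f"{path}: no gene sets found")
    return _matrix_from_pairs(pairs, system_label)


def restrict_to_list(matrix: AnnotationMatrix, gene_list: GeneList) -> AnnotationMatrix:
    """Restrict an annotation matrix to the genes of a list.

    Genes of the list absent from the matrix are reported (logged) as
    unannotated in this system and excluded: an all-zero row carries no
    clustering signal, so such genes cannot be meaningfully assigned by this
    system. Annotation columns that become all-zero are dropped.
    """
    present = [g for g in gene_list if g in matrix._gene_index]
    missing = [g for g in gene_list if g not in matrix._gene_index]
    if missing:
        logger.info(
            "%s: %d of %d list genes are unannotated in this system: %s",
            matrix.system_label,
            len(missing),
            len(gene_list),
            ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""),
        )
    if not present:
        raise ValueError(
            f"no annotated genes: the gene list shares no genes with the "
            f"{matrix.system_label!r} annotation matrix"
        )
    rows = [matrix._gene_index[g] for g in present]
    sub = matrix.incidence[rows, :]
    keep = np.flatnonzero(sub.sum(axis=0) > 0)
    return AnnotationMatrix(
        matrix.system_label,
        tuple(present),
        tuple(matrix.annotations[j] for j in keep),
        sub[:, keep],
    )


def format_p(p: float) -> str:
    """Format a probability: scientific notation below 1e-4, else decimal."""
    return f"{p:.6e}" if p < 1e-4 else f"{p:.6f}"


def write_enrichment_tsv(records, path) -> None:
    """Write enrichment records as a TSV table, one row per record.

    Rows are ordered by (level, cluster, mode, FDR p ascending, annotation
    id) so identical analyses always serialize byte-identically.
    """
    rows = [
        {
            "level": r.level_k,
            "cluster": r.cluster_index,
            "cluster_size": r.cluster_size,
            "system": r.system_label,
            "annotation": r.annotation,
            "mode": r.mode,
            "background": r.background,
            "count_in_cluster": r.a,
            "count_in_list": r.K_list,
            "list_size": r.N,
            "p_raw": r.p_raw,
            "p_fdr": r.p_fdr,
        }
        for r in records
    ]
    rows.sort(
        key=lambda d: (d["level"], d["cluster"], d["mode"], d["p_fdr"], d["annotation"])
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ENRICHMENT_COLUMNS) + "\n")
        for d in rows:
            # n column of the 2x2 table is cluster_size for cluster-vs-list
            # tests and list_size's counterpart for list-vs-genome; both are
            # carried verbatim on the record.
            fh.write(
                "\t".join(
                    [
                        str(d["level"]),
                        str(d["cluster"]),
                        str(d["cluster_size"]),
                        d["system"],
                        d["annotation"],
                        d["mode"],
                        d["background"],
                        str(d["count_in_cluster"]),
                        str(d["count_in_list"]),
                        str(d["list_size"]),
                        format_p(d["p_raw"]),
                        format_p(d["p_fdr"]),
                    ]
                )
                + "\n"
            )


def read_enrichment_tsv(path) -> list:
    """Read back a table written by :func:`write_enrichment_tsv`."""
    from .enrichment import EnrichmentRecord

    df = pd.read_csv(path, sep="\t", dtype={"system": str, "annotation": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            EnrichmentRecord(
                level_k=int(row.level),
                cluster_index=int(row.cluster),
                cluster_size=int(row.cluster_size),
                system_label=str(row.system),
                annotation=str(row.annotation),
                mode=str(row.mode),
                background=str(row.background),
                a=int(row.count_in_cluster),
                K_list=int(row.count_in_list),
                n=int(row.cluster_size),
                N=int(row.list_size),
                p_raw=float(row.p_raw),
                p_fdr=float(row.p_fdr),
            )
        )
    return records


def write_tree_json(tree, path) -> None:
    """Serialize a cluster tree (levels, members, edges, scores) as JSON.

    Edge weights and scores are written at full float precision
    (``repr``-round-trip), so deserializing reproduces the tree exactly.
    """
    if not tree.levels:
        raise ValueError("empty tree")
    payload = {
        "system_label": tree.system_label,
        "levels": [
            {
                "k_requested": lv.k_requested,
                "assignment": dict(lv.assignment),
                "objective": lv.objective,
                "seed": lv.seed,
                "n_restarts_used": lv.n_restarts_used,
            }
            for lv in tree.levels
        ],
        "edges": [
            {
                "parent_level": e.parent_level,
                "parent_cluster": e.parent_cluster,
                "child_level": e.child_level,
                "child_cluster": e.child_cluster,
                "phi": e.phi,
            }
            for e in tree.edges
        ],
        "scores": [
            {
                "level_k": s.level_k,
                "log_likelihood": s.log_likelihood,
                "n_parameters": s.n_parameters,
                "aic": s.aic,
                "daic": s.daic,
                "retained_dimensions": sorted(s.retained_dimensions)
                if s.retained_dimensions is not None
                else None,
            }
            for s in tree.scores
        ],
        "best_aic_level": tree.best_aic_level,
        "best_daic_level": tree.best_daic_level,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_tree_json(path):
    """Deserialize a tree written by :func:`write_tree_json`."""
    from .clustering import ClusteringLevel
    from .model_selection import ModelScore
    from .tree import ClusterTree, TreeEdge

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    levels = []
    for lv in payload["levels"]:
        assignment = {g: int(c) for g, c in lv["assignment"].items()}
        levels.append(
            ClusteringLevel(
                k_requested=int(lv["k_requested"]),
                assignment=assignment,
                objective=float(lv["objective"]),
                seed=int(lv["seed"]),
                n_restarts_used=int(lv["n_restarts_used"]),
            )
        )
    edges = [
        TreeEdge(
            parent_level=int(e["parent_level"]),
            parent_cluster=int(e["parent_cluster"]),
            child_level=int(e["child_level"]),
            child_cluster=int(e["child_cluster"]),
            phi=float(e["phi"]),
        )
        for e in payload["edges"]
    ]
    scores = [
        ModelScore(
            level_k=int(s["level_k"]),
            log_likelihood=float(s["log_likelihood"]),
            n_parameters=int(s["n_parameters"]),
            aic=float(s["aic"]),
            daic=None if s["daic"] is None else float(s["daic"]),
            retained_dimensions=None
            if s["retained_dimensions"] is None
            else frozenset(s["retained_dimensions"]),
        )
        for s in payload["scores"]
    ]
    return ClusterTree(
        system_label=payload["system_label"],
        levels=levels,
        edges=edges,
        scores=scores,
        best_aic_level=payload["best_aic_level"],
        best_daic_level=payload["best_daic_level"],
    )
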