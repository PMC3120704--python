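"""Non-nested cluster trees.

The clustering solutions for k = 1..Kmax are stacked into a tree-like
visualizable structure: every nonempty cluster at level k+1 is connected to
the best-correlating nonempty cluster at level k, where correlation is the
phi coefficient (Pearson correlation of binary membership indicators over
the clustered gene universe). Unlike ordinary hierarchical clustering the
levels are independent solutions, so an edge records similarity between
adjacent solutions rather than refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusteringLevel
from .model_selection import ModelScore


@dataclass(frozen=True)
class TreeEdge:
    """Edge from a child cluster at level k+1 to its best parent at level k."""

    parent_level: int
    parent_cluster: int
    child_level: int
    child_cluster: int
    phi: float

    def __post_init__(self):
        if self.child_level != self.parent_level + 1:
            raise ValueError("edges connect adjacent levels only")
        if not -1.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [-1, 1]")


@dataclass
class ClusterTree:
    """Ordered clustering levels 1..Kmax with adjacent-level edges and scores."""

    system_label: str
    levels: list[ClusteringLevel]
    edges: list[TreeEdge] = field(default_factory=list)
    scores: list[ModelScore] = field(default_factory=list)
    best_aic_level: int | None = None
    best_daic_level: int | None = None

    def level(self, k: int) -> ClusteringLevel:
        for lv in self.levels:
            if lv.k_requested == k:
                return lv
        raise KeyError(f"no level with k={k}")


def membership_phi(members_a, members_b, universe) -> float:
    """Phi coefficient between two cluster memberships over a gene universe.

    This is the Pearson correlation of the binary indicator vectors of the
    two memberships across ``universe`` — the "correlation between two
    binomial distributions representing the gene memberships". A constant
    indicator (empty or universe-covering cluster) has no variance; the
    correlation is undefined and returned as 0 by convention.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty universe")
    sa, sb = set(members_a), set(members_b)
    if not sa <= set(universe) or not sb <= set(universe):
        raise ValueError("memberships must be subsets of the universe")
    x = np.array([g in sa for g in universe], dtype=np.float64)
    y = np.array([g in sb for g in universe], dtype=np.float64)
    if x.std() == 0.0 or y.std() == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def link_adjacent(levels: list[ClusteringLevel], universe) -> list[TreeEdge]:
    """Connect every nonempty child cluster to its best-phi parent.

    For each pair of adjacent levels (k, k+1) and each nonempty cluster at
    the deeper level, one edge is drawn to the arg-max-phi nonempty cluster
    at level k; ties break toward the lower parent cluster index, so the
    construction is deterministic and guarantees single fan-in per child.
    """
    universe = list(universe)
    edges: list[TreeEdge] = []
    ordered = sorted(levels, key=lambda lv: lv.k_requested)
    for upper, lower in zip(ordered, ordered[1:]):
        parent_members = {c: upper.members(c) for c in upper.nonempty_clusters()}
        for child in lower.nonempty_clusters():
            child_members = lower.members(child)
            best_parent, best_phi = None, -np.inf
            for c in sorted(parent_members):
                phi = membership_phi(child_members, parent_members[c], universe)
                if phi > best_phi:
                    best_parent, best_phi = c, phi
            edges.append(
                TreeEdge(
                    parent_level=upper.k_requested,
                    parent_cluster=best_parent,
                    child_level=lower.k_requested,
                    child_cluster=child,
                    phi=best_phi,
                )
            )
    return edges


def build_tree(
    system_label: str,
    levels: list[ClusteringLevel],
    scores: list[ModelScore],
    universe=None,
    best_aic_level: int | None = None,
    best_daic_level: int | None = None,
) -> ClusterTree:
    """Assemble levels, scores and adjacent-level edges into a ClusterTree."""
    if universe is None:
        universe = sorted(levels[0].assignment)
    return ClusterTree(
        system_label=system_label,
        levels=sorted(levels, key=lambda lv: lv.k_requested),
        edges=link_adjacent(levels, universe),
        scores=sorted(scores, key=lambda s: s.level_k),
        best_aic_level=best_aic_level,
        best_daic_level=best_daic_level,
    )
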