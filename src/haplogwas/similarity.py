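"""Trait-by-trait haploblock similarity and bi-clustering.

Two traits are similar when the haploblocks significantly enriched for
their associated SNPs overlap: the score is the Sorensen-Dice
coefficient 2|A n B| / (|A| + |B|) of the two enriched-block sets (the
double sum of shared blocks normalized by the total enriched blocks of
the pair). Bi-clustering of the symmetric trait x trait matrix is one
average-linkage hierarchical clustering of 1 - score applied to both
axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def dice_similarity(set_a, set_b) -> float:
    """Sorensen-Dice overlap 2|a n b| / (|a| + |b|); 0 when both empty."""
    a, b = set(set_a), set(set_b)
    tot = len(a) + len(b)
    if tot == 0:
        return 0.0
    return 2.0 * len(a & b) / tot


@dataclass
class SimilarityMatrix:
    """Symmetric trait x trait Dice matrix with clustering metadata."""

    labels: list[str]
    scores: np.ndarray
    empty_traits: list[str] = field(default_factory=list)
    leaf_order: list[str] | None = None
    linkage: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        df = self.to_frame().stack().rename("score").reset_index()
        df.columns = ["trait_a", "trait_b", "score"]
        return df


def similarity_matrix(sets: dict[str, set]) -> SimilarityMatrix:
    """All pairwise Dice scores between traits' enriched-block sets.

    Traits are ordered alphabetically for deterministic downstream
    tie-breaking. A trait with an empty set gets a zero row/column
    (including the diagonal) and is flagged in ``empty_traits``.
    """
    if len(sets) < 2:
        raise ValueError("need at least two traits")
    labels = sorted(sets)
    m = len(labels)
    S = np.zeros((m, m))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels[i:], start=i):
            S[i, j] = S[j, i] = dice_similarity(sets[a], sets[b])
    empty = [t for t in labels if len(sets[t]) == 0]
    return SimilarityMatrix(labels, S, empty_traits=empty)


def bicluster(
    sim: SimilarityMatrix,
    linkage_method: str = "average",
    height_threshold: float = 0.8,
) -> SimilarityMatrix:
    """Hierarchically cluster traits on 1 - score; order rows == columns.

    Returns a new SimilarityMatrix carrying the linkage and leaf order;
    flat groups at ``height_threshold`` are available via
    :func:`flat_groups`. Ties are deterministic because traits enter in
    alphabetical order.
    """
    S = sim.scores
    if not np.allclose(S, S.T):
        raise ValueError("similarity matrix must be symmetric")
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage_method)
    order = hierarchy.leaves_list(Z)
    return SimilarityMatrix(
        labels=sim.labels,
        scores=S,
        empty_traits=list(sim.empty_traits),
        leaf_order=[sim.labels[i] for i in order],
        linkage=Z,
    )


def flat_groups(sim: SimilarityMatrix, height_threshold: float = 0.8) -> dict[str, int]:
    """Cut the dendrogram at a dissimilarity height; trait -> group id."""
    if sim.linkage is None:
        raise ValueError("run bicluster() first")
    assign = hierarchy.fcluster(sim.linkage, t=height_threshold, criterion="distance")
    return {lab: int(g) for lab, g in zip(sim.labels, assign)}


def _newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.get_left(), labels)
    right = _newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def dendrogram_newick(sim: SimilarityMatrix) -> str:
    """Newick string of the trait dendrogram (branch lengths = heights)."""
    if sim.linkage is None:
        raise ValueError("run bicluster() first")
    tree = hierarchy.to_tree(sim.linkage)
    return _newick(tree, sim.labels) + ";"
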