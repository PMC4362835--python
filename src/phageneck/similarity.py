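"""Module-similarity scoring, WPGMA clustering and query placement.

The evolutionary divergence between two phages' head-neck-tail modules
is summarized by a per-component score

    Score = Probability + 0.1 * Identity

(0-110; the 0.1 weight lets sequence identity discriminate only once the
profile-profile probability saturates at 100%), averaged over the module
components detected in *both* phages — components seen in only one are
ignored. The resulting NxN matrix of averaged scores, built per neck
Type, is clustered by WPGMA (scipy's ``weighted`` linkage) on Euclidean
distances between matrix rows; cutting the dendrogram yields the
Clusters, and a query phage is placed into the cluster with the highest
mean similarity to its members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .detection import DetectionTable, ProteinClass
from .homology import HomologyHit, HomologyProvider

logger = logging.getLogger(__name__)

__all__ = [
    "IDENTITY_WEIGHT",
    "MAX_SCORE",
    "COMPONENT_SETS",
    "component_score",
    "phage_pair_similarity",
    "SimilarityMatrix",
    "build_similarity_matrix",
    "Dendrogram",
    "wpgma_tree",
    "assign_cluster",
]

IDENTITY_WEIGHT = 0.1
MAX_SCORE = 100.0 + IDENTITY_WEIGHT * 100.0  # 110: both factors maximal

#: named component subsets for matrix construction
COMPONENT_SETS: dict[str, frozenset[ProteinClass]] = {
    "all": frozenset(ProteinClass),
    "portal": frozenset({ProteinClass.Portal}),
    "mcp-terml-portal": frozenset(
        {ProteinClass.MCP, ProteinClass.TermL, ProteinClass.Portal}
    ),
}


def component_score(hit: Optional[HomologyHit]) -> float:
    """Combined probability/identity score of one component pair (0-110).

    ``None`` (the pair was never compared) scores 0: probability 0,
    identity 0.
    """
    if hit is None:
        return 0.0
    return hit.probability + IDENTITY_WEIGHT * hit.identity


def _resolve_components(
    components: Optional[Iterable[ProteinClass] | str],
) -> frozenset[ProteinClass]:
    if components is None:
        return COMPONENT_SETS["all"]
    if isinstance(components, str):
        try:
            return COMPONENT_SETS[components]
        except KeyError:
            raise ValueError(
                f"unknown component set {components!r}; "
                f"expected one of {sorted(COMPONENT_SETS)}"
            ) from None
    return frozenset(components)


def phage_pair_similarity(
    a: str,
    b: str,
    detections: DetectionTable,
    provider: HomologyProvider,
    components: Optional[Iterable[ProteinClass] | str] = None,
) -> tuple[Optional[float], int]:
    """Mean component score between two phages over shared components.

    For every class detected in both phages (within the configured
    component subset) the combined score of the hit between the two
    proteins is computed (an uncompared pair scores 0); the mean over
    shared classes is returned with the shared-component count. Two
    identical proteins score the maximum (110). With no shared
    component, the similarity is missing: ``(None, 0)``.
    """
    subset = _resolve_components(components)
    ca = {c: e for c, e in detections.classes_of(a).items() if c in subset}
    cb = {c: e for c, e in detections.classes_of(b).items() if c in subset}
    shared = sorted(set(ca) & set(cb), key=str)
    if not shared:
        return None, 0
    scores = []
    for cls in shared:
        pa, pb = ca[cls].protein_id, cb[cls].protein_id
        if pa == pb:
            scores.append(MAX_SCORE)
        else:
            scores.append(component_score(provider.best_mutual_hit(pa, pb)))
    return float(np.mean(scores)), len(shared)


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of mean module scores between phages.

    Missing cells (no shared component) are NaN, distinct from a true 0;
    the diagonal is the maximal score (110). ``counts`` holds the
    shared-component count per cell.
    """

    ids: list[str]
    scores: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.scores.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(
            np.nan_to_num(self.scores), np.nan_to_num(self.scores.T)
        ):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(self.scores), MAX_SCORE):
            raise ValueError("diagonal must be the maximal score")

    def value(self, a: str, b: str) -> float:
        return float(self.scores[self.ids.index(a), self.ids.index(b)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.scores, index=self.ids, columns=self.ids)


def build_similarity_matrix(
    phage_ids: Sequence[str],
    detections: DetectionTable,
    provider: HomologyProvider,
    components: Optional[Iterable[ProteinClass] | str] = None,
) -> SimilarityMatrix:
    """Cross-compare all phages of one Type into an NxN score matrix."""
    ids = sorted(phage_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate phage ids")
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 phages to build a similarity matrix")
    scores = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=int)
    np.fill_diagonal(scores, MAX_SCORE)
    for i in range(n):
        counts[i, i] = len(detections.classes_of(ids[i]))
        for j in range(i + 1, n):
            s, k = phage_pair_similarity(
                ids[i], ids[j], detections, provider, components
            )
            if s is None:
                logger.warning(
                    "phages %s and %s share no module component", ids[i], ids[j]
                )
            else:
                scores[i, j] = scores[j, i] = s
            counts[i, j] = counts[j, i] = k
    return SimilarityMatrix(ids, scores, counts)


@dataclass
class Dendrogram:
    """WPGMA merge tree over the phages of one similarity matrix.

    ``merges`` is a scipy linkage array whose third column holds the
    WPGMA cluster distances; ``heights`` are the ultrametric merge
    heights (distance / 2), non-decreasing by construction.
    """

    ids: list[str]
    merges: np.ndarray
    pruned: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        h = self.heights
        if np.any(np.diff(h) < -1e-9):
            raise ValueError("WPGMA heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2] / 2.0

    def cut_k(self, k: int) -> dict[str, int]:
        """Cut into exactly ``k`` clusters (labels 1..k)."""
        labels = fcluster(self.merges, t=k, criterion="maxclust")
        return dict(zip(self.ids, (int(x) for x in labels)))

    def cut_largest_gap(self) -> dict[str, int]:
        """Cut at the largest gap between successive merge heights.

        With no discernible gap (all merges at one height) everything is
        a single cluster.
        """
        d = self.merges[:, 2]
        if len(d) == 1:
            return {pid: 1 for pid in self.ids}
        gaps = np.diff(d)
        if np.max(gaps) <= 1e-12:
            return {pid: 1 for pid in self.ids}
        i = int(np.argmax(gaps))  # first occurrence on ties
        threshold = (d[i] + d[i + 1]) / 2.0
        labels = fcluster(self.merges, t=threshold, criterion="distance")
        return dict(zip(self.ids, (int(x) for x in labels)))

    def to_newick(self) -> str:
        """Newick string with branch lengths as height deltas."""
        from scipy.cluster.hierarchy import to_tree

        # report ultrametric heights (distance / 2)
        root = to_tree(
            np.column_stack([self.merges[:, :2], self.heights, self.merges[:, 3]])
        )

        def walk(node, parent_height: float) -> str:
            if node.is_leaf():
                return f"{self.ids[node.id]}:{parent_height:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.10g}"

        if root.is_leaf():
            return f"{self.ids[root.id]};"
        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def wpgma_tree(
    matrix: SimilarityMatrix,
    distance: str = "rows",
    include_diagonal: bool = True,
) -> Dendrogram:
    """WPGMA dendrogram from a similarity matrix.

    ``distance="rows"`` (default) measures the Euclidean distance between
    matrix rows (each phage's vector of similarities to all phages,
    diagonal included unless ``include_diagonal`` is off);
    ``distance="score"`` uses the direct dissimilarity 110 - score.
    Phages with missing cells are pruned first, sparsest first, and
    reported on the result. Leaf order is lexicographic, making ties
    deterministic.
    """
    ids = list(matrix.ids)
    scores = matrix.scores.copy()
    pruned: list[str] = []
    while True:
        off = scores.copy()
        np.fill_diagonal(off, 0.0)
        missing_per_row = np.isnan(off).sum(axis=1)
        if missing_per_row.sum() == 0:
            break
        worst = int(np.argmax(missing_per_row))
        pruned.append(ids[worst])
        logger.warning(
            "pruning %s before clustering: %d missing pairs",
            ids[worst], int(missing_per_row[worst]),
        )
        keep = [i for i in range(len(ids)) if i != worst]
        scores = scores[np.ix_(keep, keep)]
        ids = [ids[i] for i in keep]
    if len(ids) < 2:
        raise ValueError("fewer than 2 phages left to cluster")

    if distance == "rows":
        feats = scores if include_diagonal else _zero_diagonal(scores)
        condensed = pdist(feats, metric="euclidean")
    elif distance == "score":
        condensed = squareform(MAX_SCORE - scores, checks=False)
    else:
        raise ValueError(f"unknown distance mode {distance!r}")
    merges = linkage(condensed, method="weighted")
    return Dendrogram(ids, merges, pruned)


def _zero_diagonal(m: np.ndarray) -> np.ndarray:
    out = m.copy()
    np.fill_diagonal(out, 0.0)
    return out


def assign_cluster(
    query_id: str,
    detections: DetectionTable,
    provider: HomologyProvider,
    reference_labels: Mapping[str, int],
    components: Optional[Iterable[ProteinClass] | str] = None,
) -> tuple[Optional[int], dict[int, float], list[str]]:
    """Place a query phage into the reference cluster it resembles most.

    The query's mean pairwise similarity to the members of each reference
    cluster is computed (pairs with no shared component are skipped); the
    cluster with the highest mean wins, ties going to the lowest cluster
    index with a warning. Returns ``(cluster, per-cluster means,
    warnings)``; cluster is ``None`` when the query shares no component
    with any reference.
    """
    warnings: list[str] = []
    by_cluster: dict[int, list[float]] = {}
    for ref_id, label in reference_labels.items():
        if ref_id == query_id:
            continue
        s, _ = phage_pair_similarity(query_id, ref_id, detections, provider, components)
        if s is not None:
            by_cluster.setdefault(label, []).append(s)
    means = {k: float(np.mean(v)) for k, v in sorted(by_cluster.items())}
    if not means:
        warnings.append(
            f"query {query_id} shares no module component with any reference; unplaced"
        )
        return None, {}, warnings
    best = max(means.values())
    winners = sorted(k for k, v in means.items() if v == best)
    if len(winners) > 1:
        warnings.append(
            f"query {query_id} equidistant to clusters {winners}; "
            f"assigned to cluster {winners[0]} (lowest index)"
        )
    return winners[0], means, warnings
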