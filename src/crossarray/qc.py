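"""Quality control of merged datasets.

The standard way to see whether platform-of-origin still dominates a merged
dataset: Euclidean sample-sample distances, average-linkage (UPGMA)
hierarchical clustering, and PCA of the gene-centered matrix.  Before
correction samples typically cluster by batch; after a successful correction
they cluster by biology.

Determinism conventions: UPGMA ties merge the pair containing the
lexicographically smallest member ID first, and each principal component's
sign is fixed so its largest-magnitude gene loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datamodel_io import MergedDataset
from .exceptions import NumericalError, ValidationError

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "euclidean_distances",
    "average_linkage_tree",
    "pca",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative sample-sample distances with zero diagonal."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValidationError("distance matrix shape does not match sample IDs")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValidationError("distances must be non-negative")
        self.matrix = m

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)


def euclidean_distances(merged: MergedDataset) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample columns."""
    if merged.values.isna().to_numpy().any():
        raise ValidationError(
            "missing values present; impute or drop incomplete features before QC"
        )
    d = squareform(pdist(merged.values.to_numpy(dtype=float).T, metric="euclidean"))
    return DistanceMatrix(sample_ids=merged.sample_ids, matrix=d)


@dataclass
class Dendrogram:
    """Binary merge tree over samples.

    ``merges`` lists (left_node, right_node, height) with nodes 0..n-1 the
    leaves (in ``leaves`` order) and node n+k the cluster created by merge k.
    Heights are cophenetic distances and are non-decreasing under UPGMA.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def cut(self, k: int) -> pd.Series:
        """Cluster labels from cutting the tree into k clusters (the last
        k-1 merges are undone)."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValidationError(f"cannot cut a {n}-leaf tree into {k} clusters")
        parent = list(range(n + len(self.merges)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for idx, (a, b, _) in enumerate(self.merges[: n - k]):
            node = n + idx
            parent[find(a)] = node
            parent[find(b)] = node
        roots = [find(i) for i in range(n)]
        relabel = {r: j for j, r in enumerate(dict.fromkeys(roots))}
        return pd.Series([relabel[r] for r in roots], index=self.leaves)

    def cophenetic(self) -> DistanceMatrix:
        """Cophenetic distances: the merge height at which two leaves join."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        out = np.zeros((n, n))
        for idx, (a, b, h) in enumerate(self.merges):
            for x in members[a]:
                for y in members[b]:
                    out[x, y] = out[y, x] = h
            members[n + idx] = members.pop(a) + members.pop(b)
        return DistanceMatrix(sample_ids=self.leaves, matrix=out)

    def to_newick(self) -> str:
        """Serialize to Newick with branch lengths from merge heights
        (leaf depth below a node equals the node's merge height)."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        for idx, (_, _, h) in enumerate(self.merges):
            height[n + idx] = h

        def render(node: int) -> str:
            if node < n:
                return _quote_newick(self.leaves[node])
            a, b, h = self.merges[node - n]
            return (
                f"({render(a)}:{h - height[a]!r},{render(b)}:{h - height[b]!r})"
            )

        return render(n + len(self.merges) - 1) + ";"


def _quote_newick(name: str) -> str:
    if any(c in name for c in "(),:;[] \t'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def average_linkage_tree(d: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomeration of a distance matrix.

    Inter-cluster distance is the mean over all cross pairs; tied minimal
    pairs are broken by the lexicographically smallest member ID (then the
    smallest ID of the partner cluster).
    """
    n = len(d.sample_ids)
    if n < 2:
        raise ValidationError("need at least two samples to cluster")
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d.matrix[i, j])
    size = {i: 1 for i in range(n)}
    min_id = {i: d.sample_ids[i] for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    next_node = n

    def get(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    while len(active) > 1:
        best: tuple[float, str, str, int, int] | None = None
        for a in active:
            for b in active:
                if b <= a:
                    continue
                key_ids = tuple(sorted((min_id[a], min_id[b])))
                cand = (get(a, b), key_ids[0], key_ids[1], a, b)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        h, _, _, a, b = best
        for c in active:
            if c in (a, b):
                continue
            new_d = (size[a] * get(a, c) + size[b] * get(b, c)) / (size[a] + size[b])
            dist[(min(c, next_node), max(c, next_node))] = new_d
        merges.append((a, b, h))
        active.discard(a)
        active.discard(b)
        size[next_node] = size[a] + size[b]
        min_id[next_node] = min(min_id[a], min_id[b])
        active.add(next_node)
        next_node += 1
    return Dendrogram(leaves=list(d.sample_ids), merges=merges)


def pca(
    merged: MergedDataset, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the per-gene mean-centered sample x gene matrix.

    Returns (sample coordinates, variance fractions).  Centering is per gene
    only (no scaling); each component's sign is fixed so its
    largest-magnitude gene loading is positive.
    """
    if merged.values.isna().to_numpy().any():
        raise ValidationError("missing values present; PCA requires a complete matrix")
    X = merged.values.to_numpy(dtype=float).T  # samples x genes
    n, g = X.shape
    max_comp = min(n - 1, g)
    if not 1 <= n_components <= max_comp:
        raise ValidationError(
            f"n_components must lie in [1, {max_comp}] for {n} samples x {g} genes"
        )
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(S ** 2))
    if total <= 0:
        raise NumericalError("constant matrix: no variance to decompose")
    # sign convention: largest-|loading| positive per component
    for k in range(n_components):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    coords = U[:, :n_components] * S[:n_components]
    frac = (S[:n_components] ** 2) / total
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return pd.DataFrame(coords, index=merged.sample_ids, columns=cols), frac
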