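"""Supervised and unsupervised clustering of complex composition.

Three views of the protein × purification abundance data:

* **supervised** — hierarchical clustering of proteins on their R² vectors
  against the eight reference sub-complexes (heat-map rows); the reference
  columns keep a fixed order.
* **Pearson-(n) PCA** — principal components of the max-normalized PAI
  matrix computed from the correlation matrix of the variables, each
  variable standardized with the population (n-denominator) standard
  deviation, which is the convention the name refers to in classical
  statistics suites.
* **UPGMA** — agglomerative clustering of proteins with the Pearson
  dissimilarity d = 1 − r across purifications and unweighted pair-group
  average linkage.

The agglomeration engine is written out explicitly so the merge order is
fully specified: among equal-distance pairs the one with the smallest
(leaf-index) pair wins.  The merge heights of UPGMA equal the average
pairwise dissimilarity between the merged groups; scipy's ``average``
linkage serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .quantify import AbundanceMatrix


class ClusteringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normalization


def max_normalize(pai: AbundanceMatrix | pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Scale each protein's PAIs so its highest value across samples is 1.

    Missing values stay missing (they are zero-imputed only at clustering
    entry).  All-missing rows are excluded and reported.
    """
    values = pai.values if isinstance(pai, AbundanceMatrix) else pai
    maxima = values.max(axis=1)
    excluded = list(values.index[maxima.isna() | (maxima <= 0)])
    kept = values.drop(index=excluded)
    return kept.div(maxima.drop(index=excluded), axis=0), excluded


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class Dendrogram:
    """An agglomeration history over named leaves.

    ``merges`` follows the scipy linkage convention: row k merges nodes
    ``a`` and ``b`` (indexes < n refer to leaves, n+k to the cluster made
    at step k) at ``height`` into a cluster of ``size`` leaves.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float, int]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def to_linkage(self) -> np.ndarray:
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def _members(self) -> dict[int, list[int]]:
        members = {i: [i] for i in range(self.n_leaves)}
        for k, (a, b, _, _) in enumerate(self.merges):
            members[self.n_leaves + k] = members[a] + members[b]
        return members

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order implied by the merge history."""
        if not self.merges:
            return list(self.leaves)
        members = self._members()
        root = self.n_leaves + len(self.merges) - 1
        return [self.leaves[i] for i in members[root]]

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into k clusters (undo the last k−1 merges)."""
        if not 1 <= k <= self.n_leaves:
            raise ClusteringError(f"cannot cut {self.n_leaves} leaves into {k} clusters")
        members = self._members()
        active = set(range(self.n_leaves))
        for j, (a, b, _, _) in enumerate(self.merges[: self.n_leaves - k]):
            active -= {a, b}
            active.add(self.n_leaves + j)
        labels: dict[str, int] = {}
        for ci, node in enumerate(sorted(active)):
            for leaf in members[node]:
                labels[self.leaves[leaf]] = ci
        return labels

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        heights = {i: 0.0 for i in range(self.n_leaves)}
        texts = {i: _escape_newick(name) for i, name in enumerate(self.leaves)}
        for k, (a, b, h, _) in enumerate(self.merges):
            node = self.n_leaves + k
            la, lb = h - heights[a], h - heights[b]
            texts[node] = f"({texts[a]}:{la:.6g},{texts[b]}:{lb:.6g})"
            heights[node] = h
        root = self.n_leaves + len(self.merges) - 1 if self.merges else 0
        return texts[root] + ";"


def _escape_newick(name: str) -> str:
    if any(c in name for c in "(),:; '"):
        return "'" + name.replace("'", "''") + "'"
    return name


def upgma(dissimilarity: np.ndarray, leaves: Sequence[str]) -> Dendrogram:
    """Unweighted pair-group average agglomeration of a dissimilarity matrix.

    At each step the closest pair of active clusters merges; the distance
    between clusters is the arithmetic mean of all leaf-pair
    dissimilarities between them.  Ties break on the smallest node-index
    pair, making the merge sequence deterministic.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(leaves):
        raise ClusteringError("dissimilarity matrix shape does not match leaves")
    if n < 2:
        raise ClusteringError("need at least 2 leaves")
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d[i, j])
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                key = (min(a, b), max(a, b))
                cand = (dist[key], key)
                if best is None or cand < best:
                    best = cand
        h, (a, b) = best
        new_size = sizes[a] + sizes[b]
        for c in active:
            if c in (a, b):
                continue
            da = dist[(min(a, c), max(a, c))]
            db = dist[(min(b, c), max(b, c))]
            dist[(min(c, next_id), max(c, next_id))] = (
                sizes[a] * da + sizes[b] * db
            ) / new_size
        merges.append((a, b, h, new_size))
        sizes[next_id] = new_size
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(list(leaves), merges)


def pearson_dissimilarity(values: pd.DataFrame) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """d = 1 − Pearson r between rows, with missing values zero-filled.

    Pairs where r is undefined (a zero-variance row) get the maximum
    dissimilarity 2 and are reported.
    """
    x = values.fillna(0.0).to_numpy(dtype=float)
    n = x.shape[0]
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    d = np.zeros((n, n))
    undefined = []
    names = list(values.index)
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] == 0 or norms[j] == 0:
                r = None
                undefined.append((names[i], names[j]))
            else:
                r = float(centered[i] @ centered[j] / (norms[i] * norms[j]))
                r = max(-1.0, min(1.0, r))
            d[i, j] = d[j, i] = 2.0 if r is None else 1.0 - r
    return d, undefined


def ahc_upgma(norm: pd.DataFrame) -> tuple[Dendrogram, list[tuple[str, str]]]:
    """UPGMA of proteins on the Pearson dissimilarity of their PAI rows."""
    if norm.shape[0] < 2:
        raise ClusteringError("need at least 2 proteins")
    d, undefined = pearson_dissimilarity(norm)
    return upgma(d, list(norm.index)), undefined


# ---------------------------------------------------------------------------
# supervised heat-map clustering


@dataclass
class SupervisedClusters:
    dendrogram: Dendrogram
    row_order: list[str]
    matrix: pd.DataFrame  # rows reordered for the heat map, columns fixed


def supervised_cluster(
    r2_matrix: pd.DataFrame,
    metric: Literal["euclidean"] = "euclidean",
    linkage: Literal["average"] = "average",
) -> SupervisedClusters:
    """Cluster heat-map rows (proteins) on their reference-R² vectors.

    Euclidean distance with average linkage on the row vectors; the
    reference columns keep their given order.  Cells must be defined
    (undefined correlations are excluded upstream).
    """
    if r2_matrix.isna().any().any():
        bad = list(r2_matrix.index[r2_matrix.isna().any(axis=1)])
        raise ClusteringError(f"undefined R² cells for rows: {bad}")
    if r2_matrix.shape[0] < 2:
        raise ClusteringError("need at least 2 rows to cluster")
    if metric != "euclidean" or linkage != "average":
        raise ClusteringError("only euclidean/average is implemented")
    x = r2_matrix.to_numpy(dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    dendrogram = upgma(d, list(r2_matrix.index))
    order = dendrogram.leaf_order()
    return SupervisedClusters(dendrogram, order, r2_matrix.loc[order])


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame  # observations × components
    loadings: pd.DataFrame  # variables × components
    explained: pd.Series  # variance fractions, summing to 1
    dropped: list[str]  # zero-variance variables


def pca_pearson(norm: pd.DataFrame) -> PCAResult:
    """Correlation-matrix ("Pearson (n)") PCA of the normalized PAI matrix.

    Observations are the rows (proteins), variables the columns (samples).
    Each variable is standardized with its population standard deviation;
    the eigendecomposition of the resulting correlation matrix gives the
    components.  Missing values are zero-imputed at entry; zero-variance
    variables are dropped and reported.  Component signs are fixed by
    making each component's largest-magnitude loading positive.
    """
    if norm.shape[0] < 3 or norm.shape[1] < 3:
        raise ClusteringError("need at least 3 observations and 3 variables")
    x = norm.fillna(0.0).to_numpy(dtype=float)
    n = x.shape[0]
    mean = x.mean(axis=0)
    std = x.std(axis=0)  # population (n-denominator)
    keep = std > 0
    dropped = list(norm.columns[~keep])
    if keep.sum() < 2:
        raise ClusteringError("fewer than 2 variables with non-zero variance")
    z = (x[:, keep] - mean[keep]) / std[keep]
    corr = z.T @ z / n
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for k in range(eigvecs.shape[1]):
        imax = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[imax, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    comps = [f"PC{i + 1}" for i in range(eigvecs.shape[1])]
    variables = norm.columns[keep]
    loadings = pd.DataFrame(eigvecs, index=variables, columns=comps)
    scores = pd.DataFrame(z @ eigvecs, index=norm.index, columns=comps)
    explained = pd.Series(eigvals / eigvals.sum(), index=comps, name="explained")
    return PCAResult(scores, loadings, explained, dropped)
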