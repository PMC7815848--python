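"""Spectral comparison of visibility graphs.

Shapes are compared through the eigenvalue spectra of the graph Laplacian
L = D - A of their unweighted visibility graphs, normalised to the largest
eigenvalue so that graphs of different sizes become comparable.  The distance
between two shapes is the two-sample Kolmogorov-Smirnov statistic between
their spectra; the resulting distance matrix feeds hierarchical
complete-linkage clustering and classical 2-D scaling.  Equal-size graphs can
additionally be compared by the rotational distance (minimum Frobenius
distance of adjacency matrices over cyclic node re-alignments), and a
modularity-guided node-merging scheme reduces a graph to a target node count
while preserving the contour order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .vgraph import VisibilityGraph


@dataclass
class Spectrum:
    """Sorted Laplacian eigenvalues of a connected graph, scaled to [0, 1]."""

    values: np.ndarray
    n: int


@dataclass
class SpectralDistanceMatrix:
    ids: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)


def _check_connected(A: np.ndarray) -> None:
    from scipy.sparse import csgraph

    ncomp, _ = csgraph.connected_components(A, directed=False)
    if ncomp != 1:
        raise ValueError("graph is disconnected; Laplacian spectrum undefined here")


def laplacian_spectrum(graph: VisibilityGraph) -> Spectrum:
    """Eigenvalues of L = D - A, ascending, normalised to the largest one."""
    A = graph.A
    if len(A) < 2:
        raise ValueError("spectrum needs at least 2 nodes")
    _check_connected(A)
    L = np.diag(A.sum(axis=1)) - A
    vals = np.linalg.eigvalsh(L)
    vals = np.clip(vals, 0.0, None)
    vals[0] = 0.0  # connected graph: exactly one zero eigenvalue
    return Spectrum(values=vals / vals[-1], n=len(vals))


def ks_distance(s1: Spectrum, s2: Spectrum) -> float:
    """Two-sample KS statistic between two eigenvalue distributions."""
    # only the statistic is used; asymptotic mode avoids the exact-p machinery
    return float(stats.ks_2samp(s1.values, s2.values, method="asymp").statistic)


def distance_matrix(graphs: list, ids: list | None = None) -> SpectralDistanceMatrix:
    """All-pairs KS distances between the Laplacian spectra of ``graphs``."""
    if len(graphs) < 2:
        raise ValueError("need at least 2 graphs to build a distance matrix")
    if ids is None:
        ids = [g.source_id or str(k) for k, g in enumerate(graphs)]
    spectra = [laplacian_spectrum(g) for g in graphs]
    n = len(spectra)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = ks_distance(spectra[i], spectra[j])
    return SpectralDistanceMatrix(ids=list(ids), d=d)


def _condensed(dm: SpectralDistanceMatrix) -> np.ndarray:
    return squareform(dm.d, checks=False)


def linkage(dm: SpectralDistanceMatrix) -> np.ndarray:
    """Complete-linkage agglomeration of the distance matrix."""
    return hierarchy.linkage(_condensed(dm), method="complete")


def cluster(dm: SpectralDistanceMatrix, k: int) -> np.ndarray:
    """Cut the complete-linkage dendrogram into ``k`` clusters.

    Labels are renumbered deterministically by first occurrence (the cluster
    of the lowest-index shape becomes 0).
    """
    n = len(dm.ids)
    if not 1 <= k <= n:
        raise ValueError(f"cluster count k={k} must be in 1..{n}")
    raw = hierarchy.fcluster(linkage(dm), t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    return labels


def dendrogram_newick(dm: SpectralDistanceMatrix) -> str:
    """Newick string of the complete-linkage dendrogram (leaf = shape id)."""
    Z = linkage(dm)
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist):
        if node.is_leaf():
            return f"{dm.ids[node.id]}:{parent_dist - node.dist:g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{parent_dist - node.dist:g}"

    return rec(tree, tree.dist) + ";"


def embed_2d(dm: SpectralDistanceMatrix) -> np.ndarray:
    """Classical metric scaling of the distance matrix to 2-D coordinates.

    Double-centres the squared distances and projects on the top-2
    eigenvectors; per axis, the sign is fixed so the largest-magnitude
    coordinate is positive.
    """
    d = dm.d
    n = len(d)
    if n < 3:
        raise ValueError("2-D embedding needs at least 3 shapes")
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (d**2) @ J
    vals, vecs = np.linalg.eigh(Bmat)
    order = np.argsort(vals)[::-1][:2]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    for axis in range(2):
        k = int(np.argmax(np.abs(coords[:, axis])))
        if coords[k, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    return coords


def rotational_distance(g1: VisibilityGraph, g2: VisibilityGraph) -> float:
    """Min Frobenius distance of adjacency matrices over cyclic alignments.

    Searches all n cyclic shifts in both traversal directions of the second
    graph's contour order; the minimum distance is divided by n.  Requires
    equal node counts - reduce the larger graph with :func:`reduce_nodes`
    first.
    """
    if g1.n != g2.n:
        raise ValueError(
            f"rotational distance needs equal node counts ({g1.n} != {g2.n}); "
            "apply reduce_nodes to the larger graph first"
        )
    n = g1.n
    A1 = g1.A
    best = np.inf
    idx = np.arange(n)
    for base in (idx, idx[::-1]):
        for shift in range(n):
            p = np.roll(base, shift)
            Ap = g2.A[np.ix_(p, p)]
            best = min(best, float(np.linalg.norm(A1 - Ap)))
    return best / n


def _modularity(A: np.ndarray, communities: list) -> float:
    """Newman-Girvan modularity of a partition of an unweighted graph."""
    two_m = A.sum()
    deg = A.sum(axis=1)
    q = 0.0
    for comm in communities:
        comm = list(comm)
        sub = A[np.ix_(comm, comm)]
        q += sub.sum() / two_m - (deg[comm].sum() / two_m) ** 2
    return q


def reduce_nodes(graph: VisibilityGraph, target_n: int) -> VisibilityGraph:
    """Merge contour-adjacent node pairs down to ``target_n`` nodes.

    At each step the contour-adjacent pair whose merge maximises the
    Newman-Girvan modularity of the resulting contour-ordered partition is
    contracted: the merged node takes the average coordinates, the union of
    edges, and recomputed Euclidean edge weights.  Contour order is preserved
    so the reduced graph remains comparable by rotational distance.
    """
    if target_n < 3:
        raise ValueError("cannot reduce below 3 nodes")
    if target_n > graph.n:
        raise ValueError("target_n exceeds the current node count")
    nodes = graph.nodes.copy()
    A = graph.A.copy()
    while len(nodes) > target_n:
        n = len(nodes)
        best_q, best_i = -np.inf, 0
        for i in range(n):
            j = (i + 1) % n
            parts = [{i, j}] + [{v} for v in range(n) if v not in (i, j)]
            q = _modularity(A, parts)
            if q > best_q + 1e-12:
                best_q, best_i = q, i
        i = best_i
        j = (i + 1) % n
        merged = (nodes[i] + nodes[j]) / 2.0
        keep = [v for v in range(n) if v != j]
        A_new = A[np.ix_(keep, keep)]
        pos_i = keep.index(i)
        union = np.clip(A[i, keep] + A[j, keep], 0, 1)
        A_new[pos_i, :] = union
        A_new[:, pos_i] = union
        A_new[pos_i, pos_i] = 0.0
        nodes = nodes[keep]
        nodes[pos_i] = merged
        A = A_new
    D = squareform(pdist(nodes))
    W = A * D
    wmax = W.max()
    edges = {(i, j) for i in range(len(nodes)) for j in range(i + 1, len(nodes)) if A[i, j]}
    return VisibilityGraph(
        nodes=nodes,
        edges=edges,
        A=A,
        W=W,
        W_scaled=W / wmax if wmax > 0 else W,
        resolution=graph.resolution,
        source_id=graph.source_id,
    )


def bhi(labels, classes) -> float:
    """Biological Homogeneity Index of a clustering against true classes.

    Mean over clusters (of size >= 2) of the fraction of member pairs sharing
    a true class label; 1.0 means every cluster is pure.
    """
    labels = np.asarray(labels)
    classes = np.asarray(classes)
    if len(labels) != len(classes):
        raise ValueError("labels and classes must have equal length")
    scores = []
    for lab in np.unique(labels):
        members = classes[labels == lab]
        if len(members) < 2:
            continue
        same = sum(a == b for a, b in combinations(members, 2))
        total = len(members) * (len(members) - 1) / 2
        scores.append(same / total)
    if not scores:
        raise ValueError("all clusters are singletons; BHI undefined")
    return float(np.mean(scores))


def write_distance_csv(path, dm: SpectralDistanceMatrix) -> None:
    import pandas as pd

    pd.DataFrame(dm.d, index=dm.ids, columns=dm.ids).to_csv(path)
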