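"""Visibility graphs of closed contours.

Nodes are placed equidistantly along the contour; two nodes share an edge when
they see each other past the contour (see :mod:`visishape.geometry`).  The
graph carries three matrix views: the unweighted adjacency ``A``, the weighted
adjacency ``W`` holding Euclidean node distances d_E, and ``W_scaled`` = W
divided by its largest entry.  ``A`` and ``W_scaled`` are scale-, rotation-
and translation-invariant descriptors of the shape; the relative completeness
delta = 2m / (n (n-1)) summarises global shape complexity (1 for convex
shapes, smaller for lobed cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csgraph
from scipy.spatial.distance import squareform, pdist

from . import geometry
from .contour import Contour

#: optimal node density along the contour, nodes per micrometre
DEFAULT_DENSITY = 0.65

#: Douglas-Peucker tolerance (px) for the raster occlusion polyline
DEFAULT_SIMPLIFY_TOL = 1.0


@dataclass
class VisibilityGraph:
    """Visibility graph of one closed shape contour."""

    nodes: np.ndarray               # (n, 2) node coordinates in contour order
    edges: set                      # unordered index pairs (i < j)
    A: np.ndarray                   # unweighted adjacency
    W: np.ndarray                   # Euclidean edge lengths d_E
    W_scaled: np.ndarray            # W / max(W)
    resolution: float = 1.0
    source_id: str = ""

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    def degree(self) -> np.ndarray:
        return self.A.sum(axis=1)


def node_spacing(resolution: float, density: float = DEFAULT_DENSITY) -> int:
    """Node spacing in pixels from image resolution and node density.

    spacing = round(1 / (density x resolution)), floored at 2 px so that a
    node never coincides with its neighbour on coarse images.
    """
    if resolution <= 0 or density <= 0:
        raise ValueError("resolution and density must be positive")
    return max(2, int(round(1.0 / (density * resolution))))


def place_nodes(contour: Contour, spacing: int) -> np.ndarray:
    """Indices of node pixels: every ``spacing``-th contour pixel from the start.

    The node count is floor(contour_length / spacing); the remainder of the
    division is absorbed by the final inter-node gap.
    """
    length = len(contour)
    if length < 3 * spacing:
        raise ValueError(
            f"contour of {length} px is too short for spacing {spacing}; "
            f"at least {3 * spacing} px are required for 3 nodes"
        )
    count = length // spacing
    return np.arange(count) * spacing


def raster_occlusion_polyline(
    contour: Contour, node_idx: np.ndarray, tol: float = DEFAULT_SIMPLIFY_TOL
) -> np.ndarray:
    """Occluding polyline for a raster contour.

    Each inter-node stretch of the pixel-centre chain is Douglas-Peucker
    simplified (nodes remain exact vertices).  This removes the sub-pixel
    staircase of rasterisation, which otherwise blocks chords grazing smooth
    walls, while straight wall stretches stay exactly collinear so that the
    intermediate-node occlusion rule still applies.
    """
    px = contour.pixels.astype(float)
    n = len(node_idx)
    pieces = []
    for k in range(n):
        a, b = int(node_idx[k]), int(node_idx[(k + 1) % n])
        if b > a:
            stretch = px[a : b + 1]
        else:  # wrap-around stretch
            stretch = np.vstack([px[a:], px[: b + 1]])
        pieces.append(geometry.simplify_polyline(stretch, tol)[:-1])
    return np.vstack(pieces)


def build_graph(
    nodes: np.ndarray,
    boundary: np.ndarray,
    resolution: float = 1.0,
    source_id: str = "",
    tol: float = geometry.TOL,
) -> VisibilityGraph:
    """Evaluate all-pairs visibility and assemble the matrix views."""
    nodes = np.asarray(nodes, dtype=float)
    n = len(nodes)
    if n < 3:
        raise ValueError("a visibility graph needs at least 3 nodes")
    edges = geometry.visibility_edges(nodes, boundary, tol=tol)
    A = np.zeros((n, n))
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    D = squareform(pdist(nodes))
    W = A * D
    ncomp, _ = csgraph.connected_components(A, directed=False)
    if ncomp != 1:
        raise ValueError(
            "visibility graph is disconnected - the contour is malformed"
        )
    wmax = W.max()
    W_scaled = W / wmax if wmax > 0 else W.copy()
    return VisibilityGraph(
        nodes=nodes,
        edges={(i, j) for i, j in edges},
        A=A,
        W=W,
        W_scaled=W_scaled,
        resolution=resolution,
        source_id=source_id,
    )


def graph_from_contour(
    contour: Contour,
    density: float = DEFAULT_DENSITY,
    spacing: int | None = None,
    simplify_tol: float = DEFAULT_SIMPLIFY_TOL,
    source_id: str = "",
) -> VisibilityGraph:
    """Visibility graph of a raster contour at the configured node density."""
    if spacing is None:
        spacing = node_spacing(contour.resolution, density)
    idx = place_nodes(contour, spacing)
    nodes = contour.pixels[idx].astype(float)
    boundary = raster_occlusion_polyline(contour, idx, tol=simplify_tol)
    return build_graph(
        nodes, boundary, resolution=contour.resolution, source_id=source_id
    )


def graph_from_points(
    points: np.ndarray, resolution: float = 1.0, source_id: str = ""
) -> VisibilityGraph:
    """Visibility graph of a synthetic coordinate shape.

    The given coordinates are used as the nodes directly (pass-through node
    placement); the occluding boundary is the polygon through them.
    """
    points = np.asarray(points, dtype=float)
    return build_graph(points, points, resolution=resolution, source_id=source_id)


def relative_completeness(graph: VisibilityGraph) -> float:
    """Relative completeness delta = 2m / (n (n-1)) of the graph."""
    n = graph.n
    if n < 2:
        raise ValueError("relative completeness needs at least 2 nodes")
    return 2.0 * graph.m / (n * (n - 1))


# ---------------------------------------------------------------------------
# serialisation

def to_networkx(graph: VisibilityGraph):
    import networkx as nx

    G = nx.Graph()
    for k, (x, y) in enumerate(graph.nodes):
        G.add_node(k, x=float(x), y=float(y), order=k)
    for i, j in sorted(graph.edges):
        G.add_edge(i, j, weight=float(graph.W[i, j]))
    return G


def write_graphml(path, graph: VisibilityGraph) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(graph), path)


def read_graphml(path) -> VisibilityGraph:
    import networkx as nx

    G = nx.read_graphml(path)
    order = sorted(G.nodes, key=lambda v: int(G.nodes[v]["order"]))
    pos = {v: k for k, v in enumerate(order)}
    nodes = np.array([[G.nodes[v]["x"], G.nodes[v]["y"]] for v in order])
    edges = {tuple(sorted((pos[u], pos[v]))) for u, v in G.edges}
    n = len(nodes)
    A = np.zeros((n, n))
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    W = A * squareform(pdist(nodes))
    wmax = W.max()
    return VisibilityGraph(
        nodes=nodes,
        edges=edges,
        A=A,
        W=W,
        W_scaled=W / wmax if wmax > 0 else W,
    )


def write_edgelist_csv(path, graph: VisibilityGraph) -> None:
    with open(path, "w") as fh:
        fh.write("i,j,weight\n")
        for i, j in sorted(graph.edges):
            fh.write(f"{i},{j},{float(graph.W[i, j])!r}\n")
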