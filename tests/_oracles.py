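"""Independent oracles and random-input generators for the test suite.

Everything here deliberately avoids the package's own code paths: visibility
is decided by shapely's exact GEOS predicates, Otsu's threshold by an
exhaustive inter-class variance scan, shortest paths by Floyd-Warshall, and
the rotational distance by explicit permutation matrices.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LinearRing, LineString, MultiPoint, Point


def oracle_visible(i: int, j: int, pts: np.ndarray) -> bool:
    """Visibility by exact geometric predicates on the node polygon.

    In general position (no collinear triples) the only 1-D overlap between a
    chord and the ring is a boundary edge itself, so adjacency is the entire
    collinear-overlap case.
    """
    n = len(pts)
    if (abs(i - j) % n) in (1, n - 1):
        return True
    seg = LineString([pts[i], pts[j]])
    inter = seg.intersection(LinearRing(pts))
    allowed = MultiPoint([Point(pts[i]), Point(pts[j])]).buffer(1e-9)
    return inter.within(allowed)


def oracle_edge_set(pts: np.ndarray) -> set:
    n = len(pts)
    return {
        (i, j) for i in range(n) for j in range(i + 1, n) if oracle_visible(i, j, pts)
    }


def random_simple_polygon(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random star-shaped (hence simple) polygon with n vertices.

    Vertices at sorted angles around the origin with random radii; all angular
    gaps below pi guarantee simplicity, which is re-checked with GEOS.
    """
    while True:
        ang = np.sort(rng.uniform(0.0, 2.0 * np.pi, n))
        gaps = np.diff(np.append(ang, ang[0] + 2.0 * np.pi))
        if gaps.min() < 0.05 or gaps.max() >= 0.95 * np.pi:
            continue
        rad = rng.uniform(2.0, 10.0, n)
        pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        if LinearRing(pts).is_valid:
            return pts


def random_convex_nodes(rng: np.random.Generator, n: int) -> np.ndarray:
    """n points in convex position: sorted angles on a random ellipse."""
    ang = np.sort(rng.uniform(0.0, 2.0 * np.pi, n))
    while np.min(np.diff(np.append(ang, ang[0] + 2 * np.pi))) < 1e-3:
        ang = np.sort(rng.uniform(0.0, 2.0 * np.pi, n))
    a, b = rng.uniform(20.0, 100.0, 2)
    return np.column_stack([a * np.cos(ang), b * np.sin(ang)])


def exhaustive_otsu(image: np.ndarray, bins: int = 256) -> float:
    """Otsu's threshold by exhaustive scan of the inter-class variance."""
    hist, edges = np.histogram(image, bins=bins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_t, best_var = centers[0], -1.0
    total = hist.sum()
    for k in range(1, bins):
        w0 = hist[:k].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:k] * centers[:k]).sum() / hist[:k].sum()
        mu1 = (hist[k:] * centers[k:]).sum() / hist[k:].sum()
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[k - 1]
    return float(best_t)


def floyd_warshall(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on a weighted adjacency matrix."""
    n = len(W)
    D = np.where(W > 0, W, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        D = np.minimum(D, D[:, k:k + 1] + D[k:k + 1, :])
    return D


def brute_rotational_distance(A1: np.ndarray, A2: np.ndarray) -> float:
    """Rotational distance via explicit permutation matrices."""
    n = len(A1)
    best = np.inf
    eye = np.eye(n)
    for reverse in (False, True):
        base = np.arange(n)[::-1] if reverse else np.arange(n)
        for shift in range(n):
            perm = np.roll(base, shift)
            P = eye[perm]
            best = min(best, float(np.linalg.norm(A1 - P @ A2 @ P.T)))
    return best / n
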