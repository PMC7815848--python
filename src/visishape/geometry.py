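"""Planar visibility predicates for nodes on a closed contour.

Two contour nodes "see" each other when the straight segment between them
neither crosses the contour polyline nor runs along a contour stretch with a
third node strictly between them.  The second clause is what distinguishes a
square from a circle: non-adjacent nodes on the same straight wall are mutually
occluded by the intermediate nodes, while any two nodes of a convex curved
shape are visible.

All predicates work on a closed polyline given as an (B, 2) float array of
vertices in traversal order (the closing edge from the last vertex back to the
first is implied).  Pixel-centre coordinates of raster contours are small
integers, so the cross products below are exact in float64; for real-valued
synthetic coordinates a relative tolerance classifies near-collinear
configurations.
"""

from __future__ import annotations

import numpy as np

#: Relative collinearity tolerance: a point is "on" a line when its distance
#: from the line is below TOL times the segment length.  Scale-invariant.
TOL = 1e-9


def _side_signs(cross: np.ndarray, thresh: float) -> np.ndarray:
    """Classify signed cross products into -1 / 0 / +1 with a dead band."""
    s = np.zeros(cross.shape, dtype=np.int8)
    s[cross > thresh] = 1
    s[cross < -thresh] = -1
    return s


def _cyclic_runs(indices: np.ndarray, period: int) -> list[np.ndarray]:
    """Group sorted indices into maximal runs of cyclically consecutive values."""
    if len(indices) == 0:
        return []
    if len(indices) == period:
        return [indices]
    breaks = np.flatnonzero(np.diff(indices) != 1)
    runs = np.split(indices, breaks + 1)
    # merge wrap-around run (… period-1) with leading run (0 …)
    if len(runs) > 1 and indices[0] == 0 and indices[-1] == period - 1:
        runs[0] = np.concatenate([runs[-1], runs[0]])
        runs.pop()
    return runs


def visible(
    i: int,
    j: int,
    boundary: np.ndarray,
    nodes: np.ndarray,
    tol: float = TOL,
) -> bool:
    """Return True when nodes ``i`` and ``j`` see each other past ``boundary``.

    Parameters
    ----------
    i, j
        Indices into ``nodes``.
    boundary
        (B, 2) closed polyline acting as the occluding wall.  For synthetic
        coordinate shapes this is the node polygon itself; for raster contours
        it is the (optionally simplified) pixel-centre polyline.
    nodes
        (n, 2) node coordinates in contour order.  Needed for the
        collinear-overlap rule: a segment that lies on the contour is only an
        edge when no third node sits strictly between its endpoints.
    tol
        Relative geometric tolerance (dead band of the orientation tests).

    The segment may touch the boundary at its own endpoints and may graze a
    boundary vertex tangentially; only transversal crossings and occupied
    collinear stretches block visibility.
    """
    a = np.asarray(nodes[i], dtype=float)
    b = np.asarray(nodes[j], dtype=float)
    P = np.asarray(boundary, dtype=float)
    B = len(P)
    u = b - a
    L2 = float(u @ u)
    if L2 == 0.0:
        raise ValueError("visibility between coincident nodes is undefined")

    rel = P - a
    cross = u[0] * rel[:, 1] - u[1] * rel[:, 0]
    s = _side_signs(cross, tol * L2)

    nxt = np.arange(1, B + 1) % B

    # --- transversal crossings of the open segment by off-line boundary edges
    straddle_ab = (s * s[nxt]) == -1
    if straddle_ab.any():
        k = np.flatnonzero(straddle_ab)
        p, q = P[k], P[nxt[k]]
        e = q - p
        ca = e[:, 0] * (a[1] - p[:, 1]) - e[:, 1] * (a[0] - p[:, 0])
        cb = e[:, 0] * (b[1] - p[:, 1]) - e[:, 1] * (b[0] - p[:, 0])
        et = tol * np.sqrt((e * e).sum(axis=1) * L2)
        sa = np.where(ca > et, 1, np.where(ca < -et, -1, 0)).astype(np.int8)
        sb = np.where(cb > et, 1, np.where(cb < -et, -1, 0)).astype(np.int8)
        if ((sa * sb) == -1).any():
            return False

    online = s == 0
    if not online.any():
        return True

    t = (rel @ u) / L2

    aligned = False
    for run in _cyclic_runs(np.flatnonzero(online), B):
        if len(run) == B:
            aligned = True
            break
        run_t = t[run]
        has_interior = bool(np.any((run_t > tol) & (run_t < 1.0 - tol)))
        overlap = False
        if len(run) >= 2:
            lo, hi = float(run_t.min()), float(run_t.max())
            overlap = (min(hi, 1.0) - max(lo, 0.0)) > tol
        if overlap:
            # segment lies along a contour stretch: the third-node rule decides
            aligned = True
        elif has_interior:
            # isolated vertex touch inside the open segment: blocks only when
            # the wall passes through the sight line (flanks on opposite sides)
            prev_idx = (run[0] - 1) % B
            next_idx = (run[-1] + 1) % B
            if s[prev_idx] * s[next_idx] == -1:
                return False

    if aligned:
        reln = np.asarray(nodes, dtype=float) - a
        crn = u[0] * reln[:, 1] - u[1] * reln[:, 0]
        tn = (reln @ u) / L2
        third = (np.abs(crn) <= tol * L2) & (tn > tol) & (tn < 1.0 - tol)
        third[i] = third[j] = False
        if third.any():
            return False
    return True


def visibility_edges(
    nodes: np.ndarray, boundary: np.ndarray, tol: float = TOL
) -> list[tuple[int, int]]:
    """All-pairs visibility edge list for ``nodes`` against ``boundary``."""
    n = len(nodes)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if visible(i, j, boundary, nodes, tol=tol):
                edges.append((i, j))
    return edges


def is_convex(points: np.ndarray, tol: float = TOL) -> bool:
    """Orientation test: all cross products of consecutive edge pairs share sign.

    Collinear triples (zero cross within tolerance) are permitted; they occur
    on polygon sides carrying several equally spaced nodes.
    """
    p = np.asarray(points, dtype=float)
    e = np.roll(p, -1, axis=0) - p
    cr = e[:, 0] * np.roll(e, -1, axis=0)[:, 1] - e[:, 1] * np.roll(e, -1, axis=0)[:, 0]
    scale = np.hypot(e[:, 0], e[:, 1])
    scale = scale * np.roll(scale, -1)
    signs = _side_signs(cr, tol * np.maximum(scale, 1e-300))
    return not (np.any(signs > 0) and np.any(signs < 0))


def simplify_polyline(points: np.ndarray, tol: float) -> np.ndarray:
    """Douglas–Peucker simplification of an *open* polyline (endpoints kept)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) <= 2 or tol <= 0:
        return pts
    keep = np.zeros(len(pts), dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, len(pts) - 1)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2:
            continue
        seg = pts[hi] - pts[lo]
        norm = np.hypot(*seg)
        mid = pts[lo + 1 : hi] - pts[lo]
        if norm == 0:
            dist = np.hypot(mid[:, 0], mid[:, 1])
        else:
            dist = np.abs(seg[0] * mid[:, 1] - seg[1] * mid[:, 0]) / norm
        kmax = int(np.argmax(dist))
        if dist[kmax] > tol:
            split = lo + 1 + kmax
            keep[split] = True
            stack.append((lo, split))
            stack.append((split, hi))
    return pts[keep]
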