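"""Synthetic shape and tissue generators.

Everything the rest of the package needs for testing is generated here:

* coordinate node sets for simple geometric shapes (triangles, quadrilaterals,
  circles/ellipses) with uniformly spaced nodes along the boundary,
* single lobed-cell contours from the star-shaped polar model
  r(theta) = R (1 + a sin(k theta)), whose k lobes and k necks have analytic
  positions, and
* rasterised multi-cell tissue phantoms (perturbed Voronoi tessellations with
  bright, blurred walls) with complete ground truth for segmentation and
  junction detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian
from skimage.morphology import skeletonize

from .contour import Contour, border_pixels, trace_boundary

TRIANGULAR = "triangular"
RECTANGULAR = "rectangular"
CIRCULAR = "circular"

_KIND_LABEL = {
    "square": RECTANGULAR,
    "rectangle": RECTANGULAR,
    "rhombus": RECTANGULAR,
    "trapeze": RECTANGULAR,
    "right_triangle": TRIANGULAR,
    "equilateral_triangle": TRIANGULAR,
    "obtuse_triangle": TRIANGULAR,
}


@dataclass
class NodeSet:
    """Ordered coordinates of a closed synthetic shape boundary."""

    points: np.ndarray
    label: str
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 3:
            raise ValueError("a node set needs at least 3 points")
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        if np.any(np.hypot(d[:, 0], d[:, 1]) == 0):
            raise ValueError("consecutive node-set points must be distinct")

    def __len__(self) -> int:
        return len(self.points)


def _rotate(points: np.ndarray, rotation: float) -> np.ndarray:
    if rotation == 0:
        return points
    c, s = math.cos(rotation), math.sin(rotation)
    return points @ np.array([[c, s], [-s, c]])


def _start_at_rightmost(vertices: np.ndarray) -> np.ndarray:
    k = np.lexsort((vertices[:, 1], -vertices[:, 0]))[0]
    return np.roll(vertices, -k, axis=0)


def _sample_polygon(vertices: np.ndarray, n_nodes: int) -> np.ndarray:
    """n_nodes points equidistant along the closed polygon boundary."""
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    perimeter = cum[-1]
    arcs = np.arange(n_nodes) * perimeter / n_nodes
    idx = np.searchsorted(cum, arcs, side="right") - 1
    idx = np.clip(idx, 0, len(seglen) - 1)
    frac = (arcs - cum[idx]) / seglen[idx]
    return closed[idx] + frac[:, None] * seg[idx]


def _polygon_vertices(kind: str, size: float, aspect: tuple[int, int]) -> np.ndarray:
    p, q = aspect
    if kind == "square":
        h = size / 2.0
        return np.array([[h, -h], [h, h], [-h, h], [-h, -h]])
    if kind == "rectangle":
        w, h = size * p / 2.0, size * q / 2.0
        return np.array([[w, -h], [w, h], [-w, h], [-w, -h]])
    if kind == "rhombus":
        d1, d2 = size * p / 2.0, size * q / 2.0
        return np.array([[d1, 0.0], [0.0, d2], [-d1, 0.0], [0.0, -d2]])
    if kind == "trapeze":
        b1, b2, h = size, size / 2.0, size / 2.0
        return np.array(
            [[b1 / 2, -h / 2], [b2 / 2, h / 2], [-b2 / 2, h / 2], [-b1 / 2, -h / 2]]
        )
    if kind == "right_triangle":
        s = size / 4.0
        return np.array([[4.0, 0.0], [0.0, 3.0], [0.0, 0.0]]) * s
    if kind == "equilateral_triangle":
        s = size
        return np.array([[s / 2, 0.0], [0.0, s * math.sqrt(3) / 2], [-s / 2, 0.0]])
    if kind == "obtuse_triangle":
        s = size / 4.0
        return np.array([[5.0, 1.5], [0.0, 0.0], [4.0, 0.0]]) * s
    raise ValueError(f"unknown polygon kind {kind!r}")


def make_regular_polygon(
    kind: str,
    n_nodes: int,
    size: float = 5.0,
    aspect: tuple[int, int] = (1, 1),
    rotation: float = 0.0,
) -> NodeSet:
    """Node set of a polygonal shape with nodes equidistant along the perimeter.

    The first node sits at the right-most vertex.  For the corner-aligned
    kinds (square, rhombus, rectangle) the node count must be divisible such
    that every corner coincides with a node: n_nodes % 4 == 0 for equal-sided
    shapes, and (p + q) must divide n_nodes / 2 for a p:q rectangle.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be at least 3")
    if kind not in _KIND_LABEL:
        raise ValueError(f"unknown polygon kind {kind!r}")
    if kind in ("square", "rhombus") and n_nodes % 4 != 0:
        raise ValueError(
            f"{kind} corners coincide with nodes only when n_nodes is a "
            f"multiple of 4 (got {n_nodes})"
        )
    if kind == "rectangle":
        p, q = aspect
        if n_nodes % 2 != 0 or (n_nodes // 2) % (p + q) != 0:
            raise ValueError(
                f"rectangle aspect {p}:{q} needs p+q={p + q} to divide "
                f"n_nodes/2={n_nodes / 2:g} for corner-aligned nodes"
            )
    vertices = _polygon_vertices(kind, size, aspect)
    vertices = _rotate(vertices, rotation)
    vertices = _start_at_rightmost(vertices)
    points = _sample_polygon(vertices, n_nodes)
    return NodeSet(points=points, label=_KIND_LABEL[kind])


def make_ellipse_nodes(
    n_nodes: int,
    semi_axes: tuple[float, float],
    rotation: float = 0.0,
    arc_samples: int = 200_001,
) -> NodeSet:
    """Nodes at equal arc-length spacing along an ellipse.

    The arc length is accumulated numerically on a dense parameter grid
    (trapezoidal rule; relative error well below 1e-6 at the default grid).
    """
    a, b = semi_axes
    if n_nodes < 3:
        raise ValueError("n_nodes must be at least 3")
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    theta = np.linspace(0.0, 2.0 * math.pi, arc_samples)
    speed = np.hypot(a * np.sin(theta), b * np.cos(theta))
    arc = np.concatenate([[0.0], np.cumsum((speed[1:] + speed[:-1]) / 2.0 * np.diff(theta))])
    targets = np.arange(n_nodes) * arc[-1] / n_nodes
    th = np.interp(targets, arc, theta)
    points = np.column_stack([a * np.cos(th), b * np.sin(th)])
    return NodeSet(points=_rotate(points, rotation), label=CIRCULAR)


def standard_shape_set(n_nodes: int = 20, size: float = 5.0) -> list[tuple[str, NodeSet]]:
    """The ten-shape synthetic benchmark set with equal node counts.

    Three triangles (right-angled, equilateral, obtuse), four quadrilaterals
    (square, 3:2 rectangle, trapeze, rhombus) and three circular shapes
    (circle, ellipse, rotated ellipse), each sampled with ``n_nodes``
    equidistant boundary nodes.
    """
    ellipse_axes = (size * 1.2, size * 0.6)
    return [
        ("right_triangle", make_regular_polygon("right_triangle", n_nodes, size)),
        ("equilateral_triangle", make_regular_polygon("equilateral_triangle", n_nodes, size)),
        ("obtuse_triangle", make_regular_polygon("obtuse_triangle", n_nodes, size)),
        ("square", make_regular_polygon("square", n_nodes, size)),
        ("rectangle", make_regular_polygon("rectangle", n_nodes, size, aspect=(3, 2))),
        ("trapeze", make_regular_polygon("trapeze", n_nodes, size)),
        ("rhombus", make_regular_polygon("rhombus", n_nodes, size, aspect=(3, 2))),
        ("circle", make_ellipse_nodes(n_nodes, (size, size))),
        ("ellipse", make_ellipse_nodes(n_nodes, ellipse_axes)),
        ("rotated_ellipse", make_ellipse_nodes(n_nodes, ellipse_axes, rotation=math.pi / 5)),
    ]


# ---------------------------------------------------------------------------
# lobed single cells

@dataclass
class LobedCell:
    """Rasterised star-shaped cell r(theta) = R (1 + a sin(k theta))."""

    contour: Contour
    mask: np.ndarray                    # filled region, indexed [y, x]
    true_lobes: np.ndarray              # (k, 2) analytic lobe-tip coordinates
    true_necks: np.ndarray              # (k, 2) analytic neck coordinates
    center: np.ndarray
    resolution: float


def make_lobed_cell(
    n_lobes: int,
    base_radius: float,
    amplitude: float,
    resolution: float = 0.2,
    seed: int | None = None,
) -> LobedCell:
    """Rasterise the polar lobed-cell model with analytic ground truth.

    ``n_lobes`` = k maxima of the radius (lobes) and k minima (necks); with
    k = 0 and amplitude 0 the model degenerates to a circle.  The boundary of
    the rasterised region is a 1-pixel-wide, 8-connected closed contour.
    """
    k, R, a = n_lobes, float(base_radius), float(amplitude)
    if k < 0:
        raise ValueError("n_lobes must be non-negative")
    if not 0 <= a < 1:
        raise ValueError("amplitude must lie in [0, 1)")
    if k > 0 and 2.0 * math.pi * R * (1.0 - a) / k < 6.0:
        raise ValueError(
            "base radius too small: adjacent lobes merge after rasterisation"
        )
    rmax = R * (1.0 + a)
    pad = 6
    size = 2 * (int(math.ceil(rmax)) + pad) + 1
    c = size // 2
    yy, xx = np.mgrid[:size, :size]
    dx, dy = xx - c, yy - c
    rr = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    mask = rr < R * (1.0 + a * np.sin(k * theta))
    contour = trace_boundary(mask, resolution=resolution)

    if k > 0:
        j = np.arange(k)
        th_lobe = (math.pi / 2.0 + 2.0 * math.pi * j) / k
        th_neck = (3.0 * math.pi / 2.0 + 2.0 * math.pi * j) / k
        lobes = np.column_stack(
            [c + R * (1 + a) * np.cos(th_lobe), c + R * (1 + a) * np.sin(th_lobe)]
        )
        necks = np.column_stack(
            [c + R * (1 - a) * np.cos(th_neck), c + R * (1 - a) * np.sin(th_neck)]
        )
    else:
        lobes = np.empty((0, 2))
        necks = np.empty((0, 2))
    return LobedCell(
        contour=contour,
        mask=mask,
        true_lobes=lobes,
        true_necks=necks,
        center=np.array([c, c], dtype=float),
        resolution=resolution,
    )


# ---------------------------------------------------------------------------
# tissue phantoms

@dataclass
class TissuePhantom:
    """Synthetic cell-wall-stained tissue image with complete ground truth."""

    image: np.ndarray                   # grayscale in [0, 1], indexed [y, x]
    resolution: float                   # micrometre per pixel
    wall_mask: np.ndarray               # 1-px ground-truth wall network
    cell_labels: np.ndarray             # integer labels, 0 = wall/background
    true_lobes: dict                    # cell id -> (k, 2) coordinates
    true_necks: dict
    true_junctions: np.ndarray          # (M, 2) wall-crossing coordinates
    seed: int

    @property
    def n_cells(self) -> int:
        return int(self.cell_labels.max())


def _merge_close_points(points: np.ndarray, radius: float = 2.0) -> np.ndarray:
    """Merge points within ``radius`` of each other to their centroid."""
    if len(points) == 0:
        return points.reshape(0, 2)
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(pts[i] - pts[j])) <= radius:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return np.array([pts[g].mean(axis=0) for g in groups.values()])


def _wall_junctions(wall: np.ndarray) -> np.ndarray:
    """Coordinates (x, y) of wall pixels with at least 3 wall 8-neighbours."""
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    nn = ndimage.convolve(wall.astype(int), kernel, mode="constant")
    ys, xs = np.nonzero(wall & (nn >= 3))
    return _merge_close_points(np.column_stack([xs, ys]), radius=2.0)


def _render_walls(
    wall: np.ndarray, rng: np.random.Generator, noise_sd: float
) -> np.ndarray:
    """Bright, slightly blurred walls over a dim cell background."""
    img = np.full(wall.shape, 0.12)
    band = ndimage.binary_dilation(wall, structure=np.ones((3, 3)))
    img[band] = 1.0
    img = gaussian(img, sigma=1.0, preserve_range=True)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def make_tissue_phantom(
    n_cells: int,
    lobed: bool = True,
    noise_sd: float = 0.0,
    resolution: float = 0.2,
    seed: int = 0,
) -> TissuePhantom:
    """Rasterised multi-cell phantom emulating a cell-wall-stained epidermis.

    Cells are the regions of a Voronoi-like tessellation of jittered seed
    points; with ``lobed=True`` each seed's distance field is modulated by a
    sinusoidal angular perturbation, producing wavy, interdigitating walls.
    A ring of guard seeds surrounds the requested cells so that every labelled
    cell is fully enclosed by walls and does not touch the image border.
    Output is bit-identical for a fixed seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    rng = np.random.default_rng(seed)

    if n_cells == 1:
        cell = make_lobed_cell(
            5 if lobed else 0, 40.0, 0.25 if lobed else 0.0, resolution=resolution
        )
        wall = border_pixels(cell.mask)
        labels = np.zeros(cell.mask.shape, dtype=int)
        labels[cell.mask & ~wall] = 1
        image = _render_walls(wall, rng, noise_sd)
        return TissuePhantom(
            image=image,
            resolution=resolution,
            wall_mask=wall,
            cell_labels=labels,
            true_lobes={1: cell.true_lobes},
            true_necks={1: cell.true_necks},
            true_junctions=np.empty((0, 2)),
            seed=seed,
        )

    grid = int(math.ceil(math.sqrt(n_cells)))
    pitch, margin = 80, 40
    size = grid * pitch + 2 * margin

    centers = []
    for gy in range(grid):
        for gx in range(grid):
            if len(centers) >= n_cells:
                break
            cx = margin + (gx + 0.5) * pitch + rng.uniform(-0.2, 0.2) * pitch
            cy = margin + (gy + 0.5) * pitch + rng.uniform(-0.2, 0.2) * pitch
            centers.append((cx, cy))
    centers = np.array(centers)

    # guard seeds claim the border region so every cell is wall-enclosed
    guards = []
    lo, hi = margin * 0.25, size - margin * 0.25
    for t in np.arange(lo, hi, pitch * 0.75):
        guards.extend([(t, lo), (t, hi), (lo, t), (hi, t)])
    guards.append((hi, hi))
    seeds = np.vstack([centers, np.array(guards)])

    amp = 0.18 if lobed else 0.0
    kk = rng.integers(4, 8, size=len(seeds))
    phase = rng.uniform(0.0, 2.0 * math.pi, size=len(seeds))

    yy, xx = np.mgrid[:size, :size].astype(float)
    dist = np.empty((len(seeds), size, size))
    for s, (cx, cy) in enumerate(seeds):
        dx, dy = xx - cx, yy - cy
        d = np.hypot(dx, dy)
        if amp > 0:
            d = d * (1.0 + amp * np.sin(kk[s] * np.arctan2(dy, dx) + phase[s]))
        dist[s] = d
    assign = np.argmin(dist, axis=0)

    wall = np.zeros((size, size), dtype=bool)
    wall[1:, :] |= assign[1:, :] != assign[:-1, :]
    wall[:, 1:] |= assign[:, 1:] != assign[:, :-1]
    wall = skeletonize(wall)

    comp, _ = ndimage.label(~wall, structure=ndimage.generate_binary_structure(2, 1))
    labels = np.zeros_like(comp)
    for cid, (cx, cy) in enumerate(centers, start=1):
        labels[comp == comp[int(round(cy)), int(round(cx))]] = cid

    image = _render_walls(wall, rng, noise_sd)

    # ground-truth junctions: wall crossings on the interior cell walls
    # (guard-band crossings near the image border carry no cell information)
    junctions = _wall_junctions(wall)
    if len(junctions):
        dist_to_cell = ndimage.distance_transform_edt(labels == 0)
        jx = np.clip(np.round(junctions[:, 0]).astype(int), 0, size - 1)
        jy = np.clip(np.round(junctions[:, 1]).astype(int), 0, size - 1)
        junctions = junctions[dist_to_cell[jy, jx] <= 5.0]
    return TissuePhantom(
        image=image,
        resolution=resolution,
        wall_mask=wall,
        cell_labels=labels,
        true_lobes={},
        true_necks={},
        true_junctions=junctions,
        seed=seed,
    )


def save_phantom(phantom: TissuePhantom, directory) -> None:
    """Write the phantom as 16-bit TIFF (image) and PNG label images."""
    import os

    import tifffile
    from PIL import Image

    os.makedirs(directory, exist_ok=True)
    tifffile.imwrite(
        os.path.join(directory, "phantom.tif"),
        np.round(phantom.image * 65535).astype(np.uint16),
        resolution=(1.0 / phantom.resolution, 1.0 / phantom.resolution),
    )
    Image.fromarray(phantom.cell_labels.astype(np.uint16)).save(
        os.path.join(directory, "labels.png")
    )
    Image.fromarray((phantom.wall_mask * 65535).astype(np.uint16)).save(
        os.path.join(directory, "walls.png")
    )
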