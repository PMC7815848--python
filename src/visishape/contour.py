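"""Ordered, closed cell contours and their pixel-level extraction.

A contour is the ordered sequence of a cell region's own border pixels (region
pixels with a 4-connected background neighbour), traversed clockwise in image
coordinates (x right, y down), starting from the right-most pixel (ties broken
by the smallest y).  Consecutive contour pixels are 8-connected and each pixel
appears once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

# Moore neighbourhood in clockwise order (dx, dy), image coords (y down).
_MOORE = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]


@dataclass
class Contour:
    """Closed, clockwise boundary of one cell.

    ``pixels`` is an (N, 2) integer array of (x, y) pixel coordinates,
    0-based, origin at the top-left corner.
    """

    pixels: np.ndarray
    resolution: float = 1.0
    cell_id: int = 0
    orientation: str = "clockwise"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValueError("contour pixels must be an (N, 2) array")

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def length_px(self) -> float:
        """Polygonal length of the closed pixel chain, in pixels."""
        d = np.diff(np.vstack([self.pixels, self.pixels[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def is_closed(self) -> bool:
        dx, dy = np.abs(self.pixels[0] - self.pixels[-1])
        return max(dx, dy) <= 1


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0].astype(float), pts[:, 1].astype(float)
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def border_pixels(region: np.ndarray) -> np.ndarray:
    """Boolean mask of region pixels with a 4-connected background neighbour."""
    region = np.asarray(region, dtype=bool)
    inner = ndimage.binary_erosion(
        region, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return region & ~inner


def trace_boundary(region: np.ndarray, resolution: float = 1.0, cell_id: int = 0) -> Contour:
    """Trace the ordered boundary of a single connected region.

    Moore-neighbour tracing with Jacob's stopping criterion, followed by
    de-duplication, clockwise orientation and rotation to the canonical start
    pixel.  ``region`` is indexed [y, x].
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("cannot trace the boundary of an empty region")
    ys, xs = np.nonzero(region)
    h, w = region.shape

    def inside(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and region[y, x]

    # start: right-most pixel, smallest y among ties
    order = np.lexsort((ys, -xs))
    sx, sy = int(xs[order[0]]), int(ys[order[0]])

    # initial backtrack: the background pixel to the right of the start
    path = [(sx, sy)]
    cur = (sx, sy)
    back = (sx + 1, sy)
    start_pair = None
    for _ in range(8 * len(xs) + 8):
        # scan Moore neighbourhood clockwise starting after the backtrack
        bdx, bdy = back[0] - cur[0], back[1] - cur[1]
        k0 = _MOORE.index((bdx, bdy))
        nxt = None
        for step in range(1, 9):
            dx, dy = _MOORE[(k0 + step) % 8]
            cand = (cur[0] + dx, cur[1] + dy)
            if inside(*cand):
                nxt = cand
                # backtrack = neighbour scanned just before the hit
                pdx, pdy = _MOORE[(k0 + step - 1) % 8]
                back = (cur[0] + pdx, cur[1] + pdy)
                break
        if nxt is None:  # isolated pixel
            break
        if start_pair is None:
            start_pair = (cur, nxt)
        elif (cur, nxt) == start_pair:
            break
        cur = nxt
        path.append(cur)
    # the trace re-enters the start; drop the duplicated tail
    if len(path) > 1 and path[-1] == path[0]:
        path.pop()
    # drop the re-entered first move if present
    if len(path) > 2 and path[-1] == path[1] and path[-2] == path[0]:
        path = path[:-2]

    pts, seen = [], set()
    for p in path:
        if p not in seen:
            seen.add(p)
            pts.append(p)
    pts = np.array(pts, dtype=int)

    if _signed_area(pts) < 0:  # enforce clockwise in image coordinates
        pts = pts[::-1]
    # canonical start pixel
    start = np.lexsort((pts[:, 1], -pts[:, 0]))[0]
    pts = np.roll(pts, -start, axis=0)
    return Contour(pixels=pts, resolution=resolution, cell_id=cell_id)


def fill_contour(contour: Contour, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Boolean mask of the pixels enclosed by (and including) the contour."""
    px = contour.pixels
    if shape is None:
        shape = (int(px[:, 1].max()) + 2, int(px[:, 0].max()) + 2)
    grid = np.zeros(shape, dtype=bool)
    grid[px[:, 1], px[:, 0]] = True
    return ndimage.binary_fill_holes(grid)


def write_contour_csv(path, contour: Contour) -> None:
    """CSV with an x,y header and a sidecar resolution metadata line."""
    with open(path, "w") as fh:
        fh.write(f"# resolution_um_per_px={contour.resolution!r}\n")
        fh.write("x,y\n")
        for x, y in contour.pixels:
            fh.write(f"{float(x)},{float(y)}\n")


def read_coords_csv(path) -> tuple[np.ndarray, float]:
    """Read an ``x,y`` coordinate CSV, returning (points, resolution)."""
    resolution = 1.0
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "resolution_um_per_px=" in line:
                    resolution = float(line.split("=", 1)[1])
                continue
            if line.lower().startswith("x,"):
                continue
            x, y = line.split(",")[:2]
            rows.append((float(x), float(y)))
    return np.array(rows, dtype=float), resolution


def read_contour_csv(path, cell_id: int = 0) -> Contour:
    pts, resolution = read_coords_csv(path)
    return Contour(pixels=pts.astype(int), resolution=resolution, cell_id=cell_id)
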