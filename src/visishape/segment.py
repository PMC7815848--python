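"""Segmentation of cell-wall-stained tissue images into labelled cells.

The pipeline mirrors standard wall-stain processing: intensity rescaling and
optional cleaning (total-variation denoising, white top-hat, histogram
equalisation, stitching-seam removal), Gaussian smoothing plus a
Hessian-eigenvalue tube filter to enhance the walls, binarisation at the mean
of Otsu's threshold and the histogram mode, skeletonisation with gap closing
and spur pruning, and finally per-cell labelling and contour extraction.
Only whole cells (not touching the image border) yield contours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw, exposure, filters, morphology, restoration, transform

from .contour import Contour, trace_boundary

#: fraction of above-mean pixels beyond which an image counts as noisy
NOISE_SCORE_THRESHOLD = 0.30

#: defaults for skeleton repair (px / degrees / px)
MAX_GAP = 10
MAX_ANGLE = 45.0
MIN_BRANCH = 15

_N4 = ndimage.generate_binary_structure(2, 1)
_N8 = ndimage.generate_binary_structure(2, 2)


@dataclass
class LabeledTissue:
    """Labelled cells plus the 1-px wall skeleton separating them."""

    labels: np.ndarray            # 0 = wall/background
    skeleton: np.ndarray
    resolution: float = 1.0
    qc: dict = field(default_factory=dict)


def _rescale(image: np.ndarray) -> np.ndarray:
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        raise ValueError("constant image cannot be preprocessed")
    return (image.astype(float) - lo) / (hi - lo)


def noise_score(image: np.ndarray) -> float:
    """Fraction of pixels above the image mean after test binarisation."""
    return float((image > image.mean()).mean())


def find_seams(image: np.ndarray, min_frac: float = 0.7) -> list:
    """Straight near-vertical/horizontal intensity seams (stitching artefacts).

    A Sobel gradient map is thresholded and scanned with a probabilistic
    Hough transform restricted to near-axial angles; only lines spanning at
    least ``min_frac`` of the image extent qualify.
    """
    edges = filters.sobel(image)
    thr = edges.mean() + 2 * edges.std()
    strong = edges > thr
    h, w = image.shape
    angles = np.concatenate(
        [np.linspace(-0.05, 0.05, 9), np.pi / 2 + np.linspace(-0.05, 0.05, 9)]
    )
    lines = transform.probabilistic_hough_line(
        strong,
        threshold=10,
        line_length=int(min_frac * min(h, w)),
        line_gap=4,
        theta=angles,
    )
    return lines


def remove_seams(image: np.ndarray, lines: list, halo: int = 2) -> np.ndarray:
    """Inpaint seam pixels from their lateral neighbourhood."""
    if not lines:
        return image
    mask = np.zeros(image.shape, dtype=bool)
    h, w = image.shape
    for (x0, y0), (x1, y1) in lines:
        # stitching seams run border to border: extend the detected segment
        dx, dy = x1 - x0, y1 - y0
        norm = max(abs(dx), abs(dy))
        if norm:
            ex0 = int(round(x0 - dx / norm * max(h, w)))
            ey0 = int(round(y0 - dy / norm * max(h, w)))
            ex1 = int(round(x1 + dx / norm * max(h, w)))
            ey1 = int(round(y1 + dy / norm * max(h, w)))
        else:
            ex0, ey0, ex1, ey1 = x0, y0, x1, y1
        rr, cc = draw.line(ey0, ex0, ey1, ex1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        mask[rr[keep], cc[keep]] = True
    mask = ndimage.binary_dilation(mask, structure=_N8, iterations=halo)
    # nearest-neighbour inpainting continues crossing walls through the band,
    # followed by smoothing restricted to the band to hide the copy seam
    _, (iy, ix) = ndimage.distance_transform_edt(mask, return_indices=True)
    out = image.copy()
    out[mask] = image[iy[mask], ix[mask]]
    blurred = filters.gaussian(out, sigma=1.0, preserve_range=True)
    out[mask] = blurred[mask]
    return out


def preprocess(
    image: np.ndarray,
    denoise: bool | None = None,
    remove_seam: bool = True,
    noise_threshold: float = NOISE_SCORE_THRESHOLD,
) -> tuple[np.ndarray, dict]:
    """Rescale to [0, 1] and apply automatically triggered cleaning steps.

    ``denoise=None`` decides from the noise score (fraction of above-mean
    pixels after a test binarisation); True/False force the branch.  Returns
    the cleaned image and a QC dictionary of the decisions taken.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    img = _rescale(image)
    qc = {"denoised": False, "seam_removed": False, "rescaled": True}
    qc["noise_score"] = noise_score(img)

    if remove_seam:
        lines = find_seams(img)
        if lines:
            img = remove_seams(img, lines)
            qc["seam_removed"] = True
            qc["n_seams"] = len(lines)

    if denoise is None:
        denoise = qc["noise_score"] > noise_threshold
    if denoise:
        img = restoration.denoise_tv_chambolle(img, weight=0.2)
        img = morphology.white_tophat(img, morphology.disk(6))
        # contrast-limited adaptive equalisation: global equalisation would
        # stretch residual background noise back across the full range
        img = exposure.equalize_adapthist(np.clip(img, 0.0, 1.0))
        img = _rescale(img)
        qc["denoised"] = True
        qc["noise_score_after"] = noise_score(img)
    return img, qc


def enhance_walls(image: np.ndarray, sigma: float = 1.0, tube_sigmas=(1.0, 2.0)) -> np.ndarray:
    """Gaussian smoothing followed by a Hessian ridge (tube) filter."""
    smoothed = filters.gaussian(image, sigma=sigma, preserve_range=True)
    ridges = filters.sato(smoothed, sigmas=tube_sigmas, black_ridges=False)
    return _rescale(ridges)


def binarize(image: np.ndarray, bins: int = 256) -> np.ndarray:
    """Threshold at the mean of Otsu's threshold and the histogram mode.

    The histogram uses ``bins`` equal bins on [0, 1]; its argmax (bin centre)
    estimates the background level.  Pixels above the threshold are wall
    candidates.
    """
    img = np.asarray(image, dtype=float)
    hist, edges = np.histogram(img, bins=bins, range=(0.0, 1.0))
    if (hist > 0).sum() < 2:
        raise ValueError("degenerate histogram: image has a single intensity level")
    peak = (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]) / 2.0
    t_otsu = filters.threshold_otsu(img, nbins=bins)
    t = (t_otsu + peak) / 2.0
    return img > t


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def _endpoints(skel: np.ndarray, exclude_border: bool = True) -> np.ndarray:
    """Skeleton pixels with exactly one neighbour.

    Endings on the image border are real walls leaving the field of view, not
    defects, and are excluded by default.
    """
    nn = _neighbor_counts(skel)
    ys, xs = np.nonzero(skel & (nn == 1))
    pts = np.column_stack([xs, ys])
    if exclude_border and len(pts):
        h, w = skel.shape
        interior = (
            (pts[:, 0] > 0) & (pts[:, 0] < w - 1)
            & (pts[:, 1] > 0) & (pts[:, 1] < h - 1)
        )
        pts = pts[interior]
    return pts


def _endpoint_direction(skel: np.ndarray, x: int, y: int, depth: int = 5) -> np.ndarray:
    """Unit vector pointing outward along the ending's local direction."""
    h, w = skel.shape
    path = [(x, y)]
    visited = {(x, y)}
    cx, cy = x, y
    for _ in range(depth):
        nxt = None
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dx == dy == 0:
                    continue
                px, py = cx + dx, cy + dy
                if 0 <= px < w and 0 <= py < h and skel[py, px] and (px, py) not in visited:
                    nxt = (px, py)
                    break
            if nxt:
                break
        if nxt is None:
            break
        visited.add(nxt)
        path.append(nxt)
        cx, cy = nxt
    tail = np.array(path[-1], dtype=float)
    head = np.array(path[0], dtype=float)
    v = head - tail
    norm = np.hypot(*v)
    return v / norm if norm > 0 else np.array([0.0, 0.0])


def close_gaps(skel: np.ndarray, max_gap: int = MAX_GAP, max_angle: float = MAX_ANGLE) -> np.ndarray:
    """Bridge endpoint pairs that are close and pointing at each other.

    Two skeleton endings within ``max_gap`` px are joined by a straight pixel
    line when their ending directions are anti-parallel within ``max_angle``
    degrees and each points toward the other ending.
    """
    out = skel.copy()
    eps = _endpoints(out)
    if len(eps) < 2:
        return out
    dirs = [_endpoint_direction(out, int(x), int(y)) for x, y in eps]
    cos_lim = np.cos(np.deg2rad(max_angle))
    candidates = []
    for i in range(len(eps)):
        for j in range(i + 1, len(eps)):
            gap = eps[j] - eps[i]
            dist = float(np.hypot(*gap))
            if dist == 0 or dist > max_gap:
                continue
            u = gap / dist
            # each ending must point toward the other within max_angle;
            # wavy walls make a strict anti-parallel test too brittle
            if float(dirs[i] @ u) < cos_lim or float(dirs[j] @ -u) < cos_lim:
                continue
            candidates.append((dist, i, j))
    candidates.sort()
    used: set[int] = set()
    for dist, i, j in candidates:
        if i in used or j in used:
            continue
        rr, cc = draw.line(int(eps[i][1]), int(eps[i][0]), int(eps[j][1]), int(eps[j][0]))
        out[rr, cc] = True
        used.update((i, j))
    return out


def prune_spurs(skel: np.ndarray, min_branch: int = MIN_BRANCH) -> np.ndarray:
    """Iteratively remove endpoint branches shorter than ``min_branch`` px.

    A spur is a chain from an (interior) endpoint to the first skeleton
    crossing; chains of ``min_branch`` px or longer, and chains that never
    reach a crossing, are kept.
    """
    out = skel.copy()
    h, w = out.shape
    changed = True
    while changed:
        changed = False
        counts = _neighbor_counts(out)
        for x, y in _endpoints(out):
            path = [(int(x), int(y))]
            visited = {path[0]}
            cx, cy = path[0]
            spur = False
            while len(path) < min_branch:
                nn = [
                    (cx + dx, cy + dy)
                    for dy in (-1, 0, 1)
                    for dx in (-1, 0, 1)
                    if not (dx == dy == 0)
                    and 0 <= cx + dx < w
                    and 0 <= cy + dy < h
                    and out[cy + dy, cx + dx]
                    and (cx + dx, cy + dy) not in visited
                ]
                if not nn:
                    break
                cx, cy = nn[0]
                if counts[cy, cx] >= 3:  # reached a wall crossing
                    spur = True
                    break
                visited.add((cx, cy))
                path.append((cx, cy))
            if spur:
                for px, py in path:
                    out[py, px] = False
                changed = True
    return out


def skeletonize_and_repair(
    binary: np.ndarray,
    max_gap: int = MAX_GAP,
    max_angle: float = MAX_ANGLE,
    min_branch: int = MIN_BRANCH,
) -> np.ndarray:
    """1-px skeleton of the wall mask with gaps closed and spurs pruned."""
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise ValueError("empty wall mask")
    skel = morphology.skeletonize(binary)
    skel = close_gaps(skel, max_gap=max_gap, max_angle=max_angle)
    skel = prune_spurs(skel, min_branch=min_branch)
    # final thinning removes the 1-px attachment nubs pruning can leave
    return morphology.skeletonize(skel)


def label_cells(skeleton: np.ndarray, resolution: float = 1.0, qc: dict | None = None) -> LabeledTissue:
    """Label 4-connected non-wall regions; border-touching regions become 0."""
    comp, n = ndimage.label(~np.asarray(skeleton, dtype=bool), structure=_N4)
    border = np.unique(
        np.concatenate([comp[0, :], comp[-1, :], comp[:, 0], comp[:, -1]])
    )
    labels = np.zeros_like(comp)
    nxt = 1
    for lab in range(1, n + 1):
        if lab in border:
            continue
        labels[comp == lab] = nxt
        nxt += 1
    return LabeledTissue(
        labels=labels, skeleton=np.asarray(skeleton, dtype=bool),
        resolution=resolution, qc=qc or {},
    )


def extract_contours(tissue: LabeledTissue) -> list[Contour]:
    """One closed clockwise contour per whole cell (border cells excluded)."""
    contours = []
    for lab in range(1, int(tissue.labels.max()) + 1):
        region = tissue.labels == lab
        if not region.any():
            continue
        contours.append(
            trace_boundary(region, resolution=tissue.resolution, cell_id=lab)
        )
    return contours


def pixel_accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """(TP + TN) / total for two binary grids of equal shape."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError("shape mismatch between predicted and truth masks")
    return float((predicted == truth).mean())


def segment_image(
    image: np.ndarray,
    resolution: float = 1.0,
    min_object: int = 64,
    **preprocess_kwargs,
) -> LabeledTissue:
    """Full pipeline: preprocess, enhance, binarise, skeletonise, label."""
    cleaned, qc = preprocess(image, **preprocess_kwargs)
    enhanced = enhance_walls(cleaned)
    binary = binarize(enhanced)
    binary = morphology.remove_small_objects(binary, max_size=min_object)
    binary = morphology.remove_small_holes(binary, max_size=min_object)
    skel = skeletonize_and_repair(binary)
    return label_cells(skel, resolution=resolution, qc=qc)
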