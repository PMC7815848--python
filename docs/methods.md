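# Methods

## Visibility graphs of closed contours

A shape is represented by its closed boundary: either a list of real-valued
coordinates (synthetic shapes) or the ordered border pixels of a segmented
cell region. Nodes are placed equidistantly along the boundary; two nodes are
connected when the open segment between them

1. has no transversal crossing with the boundary polyline (touching the
   boundary at the segment's own endpoints never blocks, and an isolated
   tangent graze of a boundary vertex does not block), and
2. if the segment runs along a collinear boundary stretch, carries no third
   node strictly between its endpoints.

Rule 2 is what separates polygons from curved convex shapes: all node pairs
of a circle or ellipse see each other (complete graph, relative completeness
δ = 2m/(n(n−1)) = 1), while nodes sharing a straight polygon side are blocked
by the nodes between them (a 20-node corner-aligned square keeps 150 of 190
edges). Orientation tests use exact float arithmetic on small-integer pixel
coordinates and a relative dead band of 1e-9 (scaled by segment lengths, so
the unweighted adjacency matrix is exactly scale- and rotation-invariant) for
real-valued coordinates.

**Raster occlusion polyline.** For raster contours the occluding wall is the
pixel-centre chain simplified per inter-node stretch with Douglas–Peucker
(tolerance 1 px, nodes kept as exact vertices). Rasterisation jitters the
chain by ±0.5 px around the underlying smooth curve; tested against the raw
chain, those wiggles properly cross any chord that grazes a smooth wall and
would disconnect near-boundary edges (a digitized circle would not even be
near-complete). The simplification removes sub-pixel staircase while keeping
straight wall stretches exactly collinear, so rule 2 still applies to them.
A digitized circle retains genuinely straight axial stretches of length
~2√R px, so a handful of along-wall chords remain correctly blocked and δ
approaches 1 from below (0.989 for R = 40 px at 8 px spacing).

**Node placement.** Spacing in pixels is round(1/(density × resolution)),
floored at 2 px, with a default density of 0.65 nodes/µm. Nodes sit at every
spacing-th contour pixel from the canonical start (right-most pixel, smallest
y on ties); the division remainder is absorbed by the last inter-node gap.
Graphs carry three matrix views: unweighted adjacency A, Euclidean-weighted
W, and W scaled to its maximum entry.

## Spectral shape comparison

Graphs are compared through the eigenvalues of the Laplacian L = D − A of the
*unweighted* adjacency (weighted spectra were not found to improve class
separation), sorted and normalised to the largest eigenvalue so that spectra
of different-sized graphs live on [0, 1]. The distance between two shapes is
the two-sample Kolmogorov–Smirnov statistic between their spectra, treating
eigenvalues as samples with ties allowed (scipy's `ks_2samp`; only the
statistic is used, so the asymptotic mode is selected). The KS statistic is a
pseudometric on spectra — symmetric, zero on identical spectra, triangle
inequality — which the suite property-tests on random spectra.

Distance matrices feed hierarchical complete-linkage clustering
(`scipy.cluster.hierarchy`, cut with `maxclust`; labels renumbered by first
occurrence) and classical metric scaling (double-centred squared distances,
top-2 eigenvectors; per-axis sign fixed so the largest-magnitude coordinate
is positive). Cluster quality against known classes is the Biological
Homogeneity Index: the mean over clusters (size ≥ 2) of the fraction of
member pairs sharing a class.

Two equal-size graphs can also be compared directly by the rotational
distance: the minimum Frobenius distance between A₁ and the cyclically
shifted (and optionally reversed) A₂ over all 2n alignments, divided by n.
To compare graphs of unequal size, `reduce_nodes` contracts one
contour-adjacent node pair at a time — the pair whose merge maximises
Newman–Girvan modularity of the resulting contour-ordered partition (ties to
the lowest index) — with averaged coordinates, union of edges and recomputed
Euclidean weights. Restricting merges to contour-adjacent pairs preserves the
cyclic node order that the rotational distance requires. On the ten-shape
benchmark the clustering stays perfect (BHI 1.0) after reducing 20 → 19 nodes
and degrades gracefully below (≈ 0.87 at 17–18 nodes).

## Local features of pavement cells

Closeness centrality C(v) = (n−1)/Σᵤ d(u,v) is computed on the weighted graph
(Dijkstra on Euclidean edge lengths). Lobes are strict local minima and necks
strict local maxima of the cyclic closeness profile within a comparison
window of ±2 nodes (configurable); plateaus collapse to their central index
(left of centre when even). Same-type candidates without an opposite
extremum between them are merged to the most extreme one, so minima and
maxima alternate along the contour. A profile whose relative range is below
1e-3 (a near-circular cell) yields no extrema.

Tri-cellular junctions are skeleton pixels with ≥ 3 skeleton neighbours
(8-connectivity), with candidates within 2 px merged to their centroid. A
called lobe is re-classified as a junction lobe when a junction lies within
3 px in both x and y of its node; junctions are consumed one-to-one, nearest
pair first.

Morphometrics: area A is the pixel count enclosed by the closed contour
(even–odd fill, contour pixels included) times resolution²; the perimeter P
is the length of the Douglas–Peucker-simplified (1 px) marching-squares
boundary of the filled region — the raw 8-connected chain length
overestimates smooth perimeters by ≈ 5.5 %, which would bias circularity
C = 4πA/P² to ≈ 0.9 for circles, while the simplified boundary gives
C = 0.99 (circle, R = 30 px) and 0.80 (square, side 100 px, π/4 ≈ 0.785),
i.e. both closed forms within ~2 %. Neck width is the Euclidean distance
between consecutive necks; lobe length is the perpendicular distance from a
lobe node to the chord joining its two flanking necks (NaN without two
distinct flanking necks). Feature vectors for downstream classifiers contain
the lobe count, six moments (mean, median, min, max, skewness, excess
kurtosis — Fisher, bias-uncorrected, 0 for zero-variance) of each of four
node centralities (closeness, degree, betweenness, eccentricity), and δ.

## Segmentation of wall-stained tissue images

Intensity is rescaled to [0, 1]; a noise score (fraction of pixels above the
image mean after a test binarisation) above 0.30 triggers denoising:
total-variation denoising, white top-hat (disk radius 6), and
contrast-limited adaptive histogram equalisation — a global equalisation
stretches residual background noise back over the full range and was measured
to destroy the segmentation (accuracy 0.90 with hundreds of spurious cells at
noise sd 0.2, vs 0.98 with CLAHE). Near-axial stitching seams are found by a
Sobel gradient map scanned with a probabilistic Hough transform restricted to
±3° of the axes; detected lines are extended border-to-border and inpainted
from nearest neighbours with band-restricted smoothing.

Walls are enhanced by Gaussian smoothing (σ = 1) plus a Hessian-eigenvalue
tube filter (`sato`, σ ∈ {1, 2}); the binarisation threshold is the mean of
Otsu's threshold and the histogram mode (256 bins on [0, 1], the mode
estimating the background level). After removal of small objects and holes
the mask is skeletonised; endpoint pairs within 10 px are bridged with a
straight pixel line when each ending points toward the other within 45°
(direction estimated over a 5-px walk back along the skeleton — a strict
anti-parallel test proved too brittle on wavy walls); endpoint branches
shorter than 15 px that reach a skeleton crossing are pruned (endings on the
image border are exempt: they are walls leaving the field of view); a final
thinning removes 1-px attachment nubs. Cells are 4-connected non-skeleton
regions; regions touching the image border are dropped, and each remaining
cell's contour is traced with Moore-neighbour tracing (clockwise in image
coordinates, starting at the right-most pixel). All repair thresholds are
package defaults, exposed in the CLI configuration and logged to the QC JSON.

## Synthetic data

The generators define the test conditions for the whole package.

- **Coordinate shape set**: three triangles (right-angled, equilateral,
  obtuse), four quadrilaterals (square, 3:2 rectangle, isosceles trapeze,
  rhombus) and three circular shapes (circle, ellipse, rotated ellipse), each
  with 20 nodes equidistant along the boundary, the first node at the
  right-most vertex. Squares/rhombi require n ≡ 0 (mod 4) and p:q rectangles
  require (p+q) | n/2 so corners coincide with nodes; ellipse nodes are
  placed at equal arc length computed by dense trapezoidal quadrature
  (relative error ≪ 1e-6).
- **Lobed cells**: the polar model r(θ) = R(1 + a·sin kθ), chosen because its
  k lobes and k necks have analytic positions; rasterised to a 1-px-wide
  8-connected contour. Construction fails loudly when rasterisation would
  merge adjacent lobes (inner arc spacing 2πR(1−a)/k below 6 px).
- **Tissue phantoms**: jittered-grid seed points tessellated by (optionally
  sinusoidally perturbed) nearest-seed assignment, giving wavy
  interdigitating walls; a ring of guard seeds keeps every labelled cell
  enclosed and off the image border. Walls are rendered as the 1-px network
  dilated by 1 px, blurred (σ = 1 px), over a dim cell background, plus
  Gaussian intensity noise; default resolution 0.2 µm/px so the default node
  density of 0.65 nodes/µm maps to 8 px spacing. Ground truth comprises the
  wall skeleton, cell labels and interior wall crossings (junctions adjacent
  to labelled cells); analytic lobe/neck truth is available for single-cell
  phantoms, while the perturbed-Voronoi walls of multi-cell phantoms have no
  closed-form lobe positions and carry junction/segmentation truth only. All
  randomness flows through one seeded generator: fixed seed, bit-identical
  output.

What the phantoms do **not** emulate: microscope optics (PSF, depth
attenuation, z-stacks), uneven staining, cytoplasmic signal, or tile
stitching beyond a single straight-seam option. Passing tests therefore
demonstrate correctness of the graph construction, comparison and feature
calling on well-posed inputs, and robustness of the segmentation to additive
Gaussian noise — not performance on real microscopy in all its failure modes.

## Numerical choices and degenerate inputs

- Geometric dead band 1e-9 (relative); exact for integer pixel coordinates.
- Laplacian eigenvalues are clipped at 0 and the smallest is pinned to 0
  (connected graphs have exactly one zero eigenvalue).
- Complete-linkage ties follow scipy's deterministic condensed ordering;
  cluster labels are renumbered by first occurrence.
- Modularity ties in node reduction go to the lowest contour index.
- Constant closeness profiles (relative range < 1e-3) produce zero lobes and
  necks rather than an error; disconnected graphs, empty masks, constant
  images and single-bin histograms raise `ValueError`.
- Segmentation of a noise-free phantom recovers the exact cell count and
  ≥ 0.99 cell-pixel agreement, but not the bit-exact wall centreline: the
  phantom renders walls as a dilated, blurred band, and re-skeletonising that
  band can sit 1 px off the generating centreline near junctions (contours
  consequently match ground truth within a 2 px Hausdorff distance).

## Problem sizes used by the test suite

Chosen so the full suite and the acceptance script each run in well under a
minute of CPU: the ten-shape benchmark at 20 nodes; 50 random convex node
sets with n ≤ 40; 100 random simple polygons with n ≤ 15 for the oracle
comparison; lobed cells with R = 60 px and k = 3…8; ten 9-cell phantoms
(~280² px) at noise sd 0.1 for segmentation accuracy.
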