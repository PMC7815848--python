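# visishape

Visibility-graph analysis of closed 2-D shapes, built for the puzzle-piece
shaped pavement cells of the leaf epidermis but applicable to any closed
contour.

A shape contour is turned into a graph: nodes are placed equidistantly along
the boundary, and two nodes are joined by an edge when they can "see" each
other — the straight segment between them neither crosses the contour nor runs
along a contour stretch occupied by a third node. Structural properties of
this graph then describe the shape:

- **Globally**, the relative completeness δ = 2m / (n(n−1)) measures how close
  the graph is to complete. Convex shapes give δ = 1; the interdigitated
  lobes and necks of a pavement cell hide nodes from one another and push δ
  down. Whole shapes are compared through the eigenvalue spectrum of the
  graph Laplacian L = D − A (normalised to the largest eigenvalue), using the
  two-sample Kolmogorov–Smirnov statistic between spectra as a size-robust
  distance; the distance matrix feeds complete-linkage clustering and
  classical 2-D scaling.
- **Locally**, the closeness centrality C(v) = (n−1)/Σᵤ d(u,v) (weighted
  shortest paths) varies along the contour: protrusion tips (lobes) are
  closeness minima, invaginations (necks) are maxima. Detected lobes that
  coincide with tri-cellular junctions (skeleton branch points where three
  cell walls meet) are reported separately from true lobes.

The package also contains a segmentation pipeline for cell-wall-stained
tissue images (tube-filter wall enhancement, Otsu/mode binarisation, skeleton
repair, per-cell contour tracing) and synthetic generators — coordinate shape
sets, star-shaped lobed cells with analytic ground truth, and multi-cell
tissue phantoms — so the whole pipeline is testable without any image data.

## Worked example

Generate the ten-shape synthetic benchmark (three triangles, four
quadrilaterals, three circular shapes; 20 boundary nodes each), build
visibility graphs, and cluster them:

```sh
visishape synth shape-set --out shapes
visishape graph --coords --out graphs shapes/*.csv
visishape compare -k 3 --out comparison graphs/*.graphml
```

The `graph` step prints one row per shape:

```
circle: n=20 m=190 delta=1.0000
ellipse: n=20 m=190 delta=1.0000
equilateral_triangle: n=20 m=145 delta=0.7632
obtuse_triangle: n=20 m=136 delta=0.7158
rectangle: n=20 m=148 delta=0.7789
rhombus: n=20 m=150 delta=0.7895
right_triangle: n=20 m=141 delta=0.7421
rotated_ellipse: n=20 m=190 delta=1.0000
square: n=20 m=150 delta=0.7895
trapeze: n=20 m=157 delta=0.8263
```

Every circular shape is convex, so all 190 = 20·19/2 node pairs see each
other and δ = 1. On a square with corner-aligned nodes, non-adjacent nodes on
the same side are blocked by the nodes between them, leaving m = 150. The
clustering in `comparison/clusters.csv` separates the three shape families
exactly (Biological Homogeneity Index 1.0).

The same machinery on a single synthetic lobed cell (polar model
r(θ) = R(1 + a·sin kθ) with k = 5, R = 40 px, a = 0.3):

```python
import visishape as vs

cell = vs.make_lobed_cell(5, 40.0, 0.3, resolution=1.0)
graph = vs.graph_from_contour(cell.contour, spacing=8)
ann = vs.annotate_cell(cell.contour, graph)
print(f"n={graph.n} m={graph.m} delta={ann.delta:.3f} "
      f"lobes={len(ann.lobes)} necks={len(ann.necks)} "
      f"circularity={ann.circularity:.3f}")
```

prints

```
n=40 m=513 delta=0.658 lobes=5 necks=5 circularity=0.501
```

— all five lobes and necks are recovered at the analytic positions, and both
complexity measures (δ and circularity 4πA/P²) reflect the lobed outline.

For raster images, `visishape segment` converts a wall-stained tissue image
into labelled cells and contour CSVs, and `visishape features` produces
per-cell morphometrics (area, perimeter, circularity, lobe lengths, neck
widths), annotated overlays and fixed-order feature vectors for downstream
classifiers. Node spacing defaults to 0.65 nodes/µm of contour, converted to
pixels via the image resolution.

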