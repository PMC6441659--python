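# Methods

`shrubshape` quantifies the architecture of shrub crops (developed around
highbush/rabbiteye blueberry) from terrestrial 3D point clouds, with the
goal of scoring bushes for over-the-row (OTR) mechanical harvesting. An OTR
harvester straddles the row; its catch plates close around the *crown* (the
stem region near the ground), so a narrow crown reduces ground loss, and a
*vase-shaped* canopy (widest near the top) shortens the fruit drop. The
pipeline measures both properties, plus conventional size traits, from a
single field scan.

## Pipeline model

1. **Rigid alignment.** The ground plane is estimated by sample consensus
   (random 3-point hypotheses scored with a truncated quadratic loss at the
   inlier tolerance, then a least-squares refit on inliers) and rotated
   parallel to the x-y plane via rotations about x and y. The planting-row
   direction is found on a 0.5 m depth raster (per-cell maximum height):
   cells more than 0.3 m above ground are bush pixels, and a Hough transform
   over them votes for the row line; a final rotation about z puts rows
   along +x. Because the 0.5 m accumulator resolves blob-like bushes only to
   a few degrees at small field sizes, the heading is refined from the bush
   points themselves: points are split into rows by an across-row occupancy
   histogram and each elongated row contributes its principal-axis
   direction (outlier-sparse bins are ignored). The transform is a pure
   rotation plus a vertical shift placing the ground inliers at z ≈ 0; it
   preserves pairwise distances exactly.
2. **Per-bush cleaning.** Inside each user-supplied (or generator-supplied)
   bounding box: (a) *adaptive ground removal* — a 0.01 m height histogram
   is built and the threshold is the smallest bin lower-limit above the
   steepest-descent bin whose count gradient is nonzero but below the noise
   factor t = 5; points below it are ground. This handles uneven mulched
   ground that defeats plane-based removal. (b) *statistical outlier
   removal* — a point is noise when its mean distance to its k = 10 nearest
   neighbours exceeds the cloud-wide mean by more than n = 1 standard
   deviations. (c) *largest DBSCAN cluster* — density clustering (defaults
   eps = 0.10 m, 10 points; these are configuration, not protocol) keeps the
   biggest cluster, discarding weed clusters the SOR filter cannot touch.
3. **Size traits.** Height/WIR/WAR are the z/x/y extents. Volumes come from
   the 3D convex hull and a Delaunay alpha shape (tetrahedra with
   circumradius ≤ 1/α, default α = 1 m⁻¹), so convex ≥ concave always.
4. **Crown size.** The crown is the across-row diameter 0.15 m above the
   bush base. A ±0.01 m slab of points is projected to the plane; distances
   to the slab's componentwise-median center are histogrammed at 0.05 m,
   clusters are split at (run-aware) local minima, and only the first
   cluster survives, trimmed at its 95th-percentile distance — this drops
   outlying branches and, for leaning bushes, displaced canopy. The
   smallest axis-aligned ellipse covering ≥ 90% of the retained points
   (minimizing d_x + d_y, centered at the retained points' mean) is found
   by an exact profile search: d_x is scanned over a 1 mm lattice and the
   minimal feasible d_y for each d_x is a closed-form order statistic. This
   is deterministic and globally optimal — a descent method can stall on
   the staircase-shaped feasible set. The crown size is the ellipse's
   across-row diameter d_y.
5. **Across-row silhouette.** The clean cloud is projected to the y-z plane
   and rasterized at 0.01 m/pixel (top-left origin, rows grow downward),
   closed morphologically (padded first so the border cannot erode), holes
   filled, largest component kept.
6. **Landmarks.** Eleven landmark points: bush top center (P1), widest-row
   ends (P2/P3; ties take the uppermost row), extreme left/right (P4/P5),
   bottom-row ends and center (P8/P9/P10), crown-canopy separation points
   (P6/P7) and canopy-bottom center (P11). Construction lines: the vertical
   center line through P9, horizontal border lines through the lower of
   P2/P4 (and P3/P5), and outer boundary lines L1/L2 from the bottom
   corners to those anchors. P6 is sought among skeleton endpoints
   (morphological thinning; an endpoint has one 8-connected neighbour;
   branches shorter than 5 px are rasterization spurs and are pruned) in
   the lower-left quadrant: candidates must lie above L1, within one MAD of
   the maximal distance to L1, and above the median + MAD of the quadrant's
   distance population; the candidate closest to the bush bottom wins. P7
   mirrors on the right. The separation row is the lower of P6/P7; with
   neither found, P11 falls back to P9 (no distinguishable stem region).
7. **Canopy shape (path curve).** The canopy contour (mask above the
   separation row) is fitted with a one-parameter family of closed
   symmetric curves: λ = 1 is a circle, λ < 1 vase-shaped, λ > 1 conical
   (see `pathcurve.py` for the parametric form; the curve's width and
   height are free scales, and the fitted position offsets are a rigid
   translation). The fit minimizes an energy equal to
   sqrt(Σ distances)/n over the rendered curve's pixels, where each
   distance is to the nearest contour pixel (computed via a precomputed
   exact distance transform; a KD-tree handles off-canvas pixels).
   Multi-start finite-difference gradient descent: w and h start on a grid
   from half to the full canopy bounding box in 5 px steps, λ starts at 1
   (unbiased between vase and conical), offsets at the canopy's top
   center; a step is accepted when the energy drops by ≥ 1e-6, otherwise
   the learning rate halves; a start stops after 5 stalls or 500
   iterations. The lowest-energy start wins; the whole fit is
   deterministic.
8. **Shape indices.** NBR = stem height fraction h_n/h_bush; VR =
   h_upper/h_lower around the widest row; AR = fitted height/width; CN =
   fraction of the fitted-curve area outside the two canopy triangles
   (P1,P2,P3) and (P11,P2,P3); IRR = fraction of the canopy silhouette
   outside the fitted curve region (a set difference, so IRR ∈ [0, 1]).
9. **Assessment.** Bushes are classified on (crown, λ): *ideal* needs
   crown < 20.32 cm and λ < 1; *acceptable* allows crown < 30.48 cm and
   λ < 1.1. Comparisons are strict; the scatter tool plots crown size
   against ln λ with guide lines at both levels and per-group mean centers.
   Validation metrics (R², RMSE, MAE, MRE) use simple linear regression;
   zero-reference pairs are excluded from MRE with a warning.

## Synthetic data

The generator builds bushes with fully known truth: a canopy sampled on the
surface of revolution of a path curve with chosen (w, h, λ) —
area-weighted along the profile, surface-only, as a scanner sees — above a
crown that is either one cylinder of the stated diameter (envelope known
exactly at every height) or several thin vertical canes on a ring, phased
so no cane hides the canopy's bottom tip in the across-row projection.
Optional short laterals (hanging below the canopy underside and poking
outward from canes) emulate the fruiting shoots of real bushes; they are
what gives the silhouette skeleton the endpoint population the P6/P7 rule
requires. Isotropic Gaussian jitter, scattered outliers and a rigid lean
about the base complete a bush. Fields place bushes in rows on a tilted,
rough plane with dense ground sampling, low weed clusters (kept below the
0.3 m bush-pixel threshold, matching the assumption that only bushes
exceed it) and per-point labels (ground/bush/weed/outlier) so segmentation
can be scored exactly. The reference-volume oracle slices a cloud into
5 cm layers, treats each as a cylinder with diameter equal to the mean of
the layer's x- and y-extents (the point-cloud analogue of a girth tape),
and sums the layers.

Default study conditions: field bushes use 3 000 points/m² of surface
(keeps a six-bush field around 10⁵ points); crown-recovery studies use
20 000 points/m² (≈7 mm spacing, typical of close-range handheld scans on
stems) with 5 mm jitter. Problem sizes in the test-suite studies — 20
bushes for crown recovery, 25 silhouettes (5 λ values × 5 seeds) for
shape-class recovery, 2×3-bush fields for segmentation — were chosen as the
smallest sets that exercise the full parameter ranges.

## What the synthetic tests do and do not show

Generated bushes are smooth surfaces of revolution: no occlusion, no leaf
or branch organs, no multi-scan registration error. Passing recovery tests
shows the algorithms are correct on geometry whose truth is known, not that
field accuracy will match; conversely the known limitations below are
visible precisely because truth is known.

- The covering-ellipse objective spends its allowed 10% exclusion on the
  in-row extremes and must then cover nearly the full across-row spread, so
  on a thin noisy ring it overestimates d_y by roughly 3σ of the point
  jitter. Real multi-cane cross-sections are less hollow and less affected.
- The crown is measured 0.15 m above the *cleaned cloud's* minimum z; on
  rough ground the adaptive threshold can sit several centimeters above the
  true stem base, shifting the slab upward correspondingly.
- The P6/P7 separation rule assumes a richly structured silhouette; on
  sparse synthetic bushes its median+MAD floor often rejects all candidates
  (with ≤ 2 quadrant endpoints it mathematically must), and the
  conservative fallback (P11 = P9, NBR = 0) engages. The λ fit then spans
  the whole silhouette including the stem, biasing λ toward 1 for stemmed
  bushes.
- Hough row detection needs ≥ 2 bushes per row; the principal-axis
  refinement needs rows longer than they are thick.

## Numerical choices

- Plane fit: tolerance 0.03 m (nominal scanner accuracy), 1000 seeded
  iterations; the seed is configuration.
- Ellipse search lattice 1 mm; the minimal d_y is rounded up to the
  lattice so the reported pair is always feasible.
- Path-curve parameter domain t ∈ [−20, 20]; rendering oversamples so
  adjacent samples land on adjacent pixels (gap-free closed loop);
  finite-difference steps 1 px (w, h, offsets) and 0.01 (λ); lower bounds
  w, h ≥ 3 px, λ ≥ 0.02 keep t_max defined.
- Cluster-size ties in DBSCAN selection go to the cluster containing the
  lowest point index; widest-row ties to the uppermost row — determinism
  over physical meaning in degenerate cases.
- Degenerate inputs: coplanar clouds get zero hull volumes with a warning;
  an empty crown slab, an all-ground threshold or a mask under 3 rows raise
  with the offending quantity in the message.

## Reproducibility

Every random choice flows from an explicit seed (`BushSpec.seed`,
`FieldSpec.seed`, the plane-fit seed, `RunConfig.seed` fanned out to
stages by fixed offsets). The path-curve and ellipse fitters contain no
randomness. Two runs of `run_pipeline` with the same config produce
bit-identical CSVs, and a run whose later outputs are deleted resumes from
the first missing stage using the manifest.
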