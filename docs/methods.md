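# Methods

## Scope and model

`myonet` quantifies the architecture of transverse muscle-biopsy sections.
Its inputs are RGB immunofluorescence images in which the green channel
carries anti-collagen VI staining (endomysium/perimysium outlining every
fiber), the red channel carries anti-slow-myosin (type I fibers bright,
type II dark), and severity is expressed as the distance of an image's
projection, in the PCA space of discriminant features, from the centroid of
control images. The pipeline has five stages — segmentation, network
construction, feature extraction, wrapper feature selection, severity
scoring — each usable on its own.

## Segmentation

Fibers are dark valleys of the green channel G, separated by bright
collagen walls.

* **Suppression depth h.** All regional minima of depth ≤ h are suppressed
  with the h-minima transform, the morphological reconstruction-by-erosion
  of G + h over G. h defaults to half the mean intensity of G, which ties
  the suppression depth to the image's collagen content; it can be
  overridden (`h_override`). Note the transform raises every surviving
  basin floor by h; composition obeys HMIN_a∘HMIN_b = HMIN_{a+b} (it is not
  idempotent).
* **Markers.** Internal markers are the regional minima (4-connected flat
  zones) of the h-minima image; components smaller than `min_marker_area`
  (default 30 px) are treated as noise. Because h scales with collagen
  content, images with very thin collagen can have h comparable to the
  pixel noise; a Gaussian blur (σ = 1 px, applied only for marker
  derivation) prevents single fiber valleys from fragmenting. External
  markers are the watershed ridge lines of the distance transform of the
  internal-marker mask, plus the 1-px image border.
* **Watershed.** The morphological gradient (dilation − erosion, 3×3
  cross) of the raw G channel is flooded from the internal markers and the
  external marker set jointly (4-connected). The external basin is the
  collagen/background (label 0); each fiber label therefore stops at the
  gradient crest along its own contour. Labels are consecutive from 1;
  labels touching the ROI border are flagged and excluded from per-image
  statistics but kept as network padding, since removing them would bias
  the neighbor counts of interior fibers.
* **Geometry and typing.** Per fiber: area A2, ellipse axes from the
  normalized second central moments, orientation of the major axis relative
  to the image x-axis in (−90°, 90°], convexity (area / convex-hull area),
  eccentricity. Typing threshold on per-fiber mean red: Otsu when the
  per-fiber means span more than 50 intensity levels (a bimodal cohort),
  otherwise a fixed mid-range fallback of 115 (halfway between the nominal
  slow ≈ 200 and fast ≈ 30 rendering levels), so single-type images do not
  get split by Otsu on noise.

## Muscle network

Every collagen pixel is assigned to its nearest fiber (Euclidean distance
transform with index return), producing a mosaic partition with no
unassigned pixels. A1 is the area of a fiber's mosaic cell *including* the
fiber, so A1/A2 ≥ 1 always, ≈ 1 for a healthy thin-walled mosaic, and grows
with endomysial fibrosis; this makes the index scale-free. Two fibers are
adjacent when their mosaic cells share at least `min_contact_px` (default
1) 4-neighbor pixel contacts. Edge weight is the centroid-to-centroid
distance in pixels; node strength (summed incident weights) then acts as an
index of fiber packing. Adjacency from 4-neighbor contacts of a planar
partition keeps the graph planar (|E| ≤ 3|V| − 6 is asserted in tests).

## The 82-feature catalog

The catalog (machine-readable via `myonet.features.catalog()`) is fixed:

| slots | group | content |
|---|---|---|
| 1–6 | size | mean/sd of area, major axis, minor axis |
| 7–14 | shape | mean/sd of axis ratio, convexity, orientation, eccentricity |
| 15–16 | collagen | mean/sd of per-fiber A1/A2 |
| 17–24 | neighborhood | degree stats overall, per type, per neighbor type |
| 25–38 | relation | each geometric quantity ÷ neighbor mean (mean/sd) |
| 39–68 | graph, per node | strength, clustering, eccentricity, betweenness, mean shortest path × {all, slow, fast} × {mean, sd} |
| 69–78 | graph, scalars | radius, diameter, efficiency, degree–weight Pearson, algebraic connectivity, s-metric, assortativity, density, transitivity, modularity |
| 79–82 | graph, subgraphs | density and modularity of the slow-only and fast-only induced subgraphs |

Conventions: all standard deviations are population (ddof = 0); the
orientation angle, axial with period 180°, uses circular mean/sd (computed
on doubled angles); shortest-path quantities are unweighted while strength
uses edge weights; betweenness is normalized by (n−1)(n−2)/2;
modularity uses deterministic greedy agglomeration (CNM) on the unweighted
graph; the degree–weight "Pearson" is the correlation between a node's
degree and its mean incident edge weight. On a disconnected network,
eccentricity/radius/diameter are computed on the largest component and
flagged; efficiency counts unreachable pairs as 0. Entries that cannot be
computed (a fiber type absent, a graph below 3 nodes, an isolated node's
relation, a zero-variance correlation) are flagged undefined and carried as
NaN — never silent zeros. Per-image statistics run over interior
(non-border) fibers; whole-network scalars use the full graph including
padding nodes.

Every graph family is cross-checked in the test suite against brute-force
oracles (exhaustive shortest-path enumeration, explicit triangle counts,
an independent Fiedler-value solver, the modularity formula applied to the
returned partition) on random planar (Delaunay) graphs, to 1e-9.

## Fuzzy-ARTMAP

The simplified single-ART supervised variant: inputs are min-max rescaled
(bounds from the training set; test values clipped) and complement coded,
category choice is T_j = |I ∧ w_j| / (α + |w_j|), resonance requires
|I ∧ w_j| / M ≥ ρ, a class mismatch raises ρ to the current match + ε and
the search continues, and learning is w ← β(I ∧ w) + (1 − β)w. An
uncommitted node (weights all ones) competes with T = M / (α + 2M).
Defaults: α = 0.001, β = 1 (fast learning), ρ_baseline = 0, ε = 0.001,
max 10 epochs (training also stops at the first epoch with no weight
change). With fast learning on consistent data, match tracking eventually
commits point categories wherever boxes of different classes overlap, which
yields the 100% resubstitution property asserted in the tests. Presentation
order matters; dataset order is the default, with an optional seeded
shuffle and a majority-voting mode over several shuffled learners.

## Feature selection

Subset quality is the mean held-out error over a stratified k-fold split
(per-class disjoint subsets rotated through validation). The default is
k = 4: each class is split into four disjoint subsets, three train and one
validates, rotating until every subset has validated once. ARTMAP's
rescaling bounds are fit inside each training fold (no leakage). SFS adds
the error-minimizing feature (ties → lowest catalog index) and stops when
the best addition strictly increases the error or the error reaches zero;
SBS mirrors it top-down, discarding while the error does not increase.
Greedy search can miss jointly-informative pairs (an XOR pair); this is an
accepted property of the method, and results are bit-reproducible given
(data, k, params, seed).

## Severity scoring

Selected features of all training images are z-scored (zero-variance
features pass through unscaled) and projected on principal components —
3 when ≥ 4 features are selected, else 2; selections no larger than the
component count are used unprojected. The PCA basis is fit on all training
images by default (`fit_on="controls"` switches to controls only). The
control centroid is the mean projection of control images; an image's
severity is its Euclidean distance from that centroid, and Pearson R with
two-sided t-test p-values relates distance to integer grades 1–4.
Classification of a new image runs a triple control/MD/NA comparison and
two pairwise comparisons, each with its own selected features and trained
ARTMAP; a mixed pattern is reported when the pairwise verdicts contradict
the triple label, and a near-boundary flag is raised when the triple
distance falls below the 10th percentile of the pathological training
distances.

## Synthetic biopsies

The generator emulates what the pipeline measures, not histology per se:

* **Tessellation.** Voronoi cells of a hexagonal lattice jittered uniformly
  by `size_cv` × half the lattice spacing — healthy muscle's polygonal,
  homogeneous mosaic at `size_cv` ≈ 0.1, strongly heterogeneous at 0.6+.
* **Fibrosis.** Each cell is eroded by `fibrosis` px (collagen band
  half-width) and corner-rounded by an opening whose radius is `roundness`
  × half the remaining inradius; an erosion that empties a fiber raises a
  degenerate-tessellation error naming the offending parameters.
* **Typing.** Slow fibers are the `slow_fraction` quantile of a per-fiber
  score blending iid noise with a smooth random field (two long-wavelength
  cosines, 1–2 image widths); `grouping` interpolates between a random
  mosaic and contiguous same-type patches, with the slow count held fixed.
* **Rendering.** Collagen green 200, fiber green 20; slow red 200, fast red
  30; blue 10; additive Gaussian noise (`noise_sd`, default 5) clipped to
  8 bits. The wide red margin makes fiber typing robust to noise ≤ 20.
* **Ground truth.** Fiber label map, full cell partition, types, cell
  adjacency, border ids, and `severity_param` — the mean of
  (fibrosis/10, size_cv, roundness), a single known scalar for recovery
  experiments (10 px is the reference band width; spec validation caps the
  band below a tenth of the frame).

Default frame: 320 × 320 px with 49 fibers — a scaled-down field chosen so
that full cohorts re-run in minutes; phenotype presets (`make_spec`)
give control, dystrophic (fibrosis + heterogeneity + rounding ramp) and
neurogenic (grouping-dominated, geometry near control) images, and the
experiment module also draws cohorts with within-class parameter spread, as
real cohorts spanning ages and muscles would show.

What the generator does **not** model: staining artifacts and uneven
illumination, perimysial fascicle boundaries, per-group angulated atrophy
(grouping and atrophy dials are independent), sectioning obliqueness, and
human ROI choice (frames are artifact-free by construction). Passing the
synthetic validation therefore demonstrates the correctness and sensitivity
of the machinery — segmentation recovery, monotone response of the fibrosis
and grouping indices, end-to-end severity recovery with median R ≥ 0.8 —
but not clinical performance on real biopsies, which requires clinical
material and pathologist grades.

## Numerical choices and degenerate inputs

* Watershed and labeling are 4-connected throughout; all stages are
  deterministic given the input image and seeds.
* Regional minima are extracted by reconstruction with an infinitesimal
  lift (1e-6), robust for 8-bit-scale intensities.
* Ties in ARTMAP category choice and in SFS/SBS go to the lowest index.
* An all-zero G channel yields h = 0 and is handled without division by h.
* Fibers with zero minor axis (degenerate single-row regions) get an
  undefined axis ratio rather than an infinity.
* Relation features skip nodes whose neighbor mean is numerically zero
  (relevant for the signed orientation angle).

## Known limitations

* The catalog's relation of orientation angles (slots 35–36) is a signed
  ratio and noisy around small neighbor means; it is retained for layout
  fidelity but rarely informative.
* SFS's plateau rule (additions that leave the error unchanged are kept)
  can produce large selected sets on small cohorts where the CV error
  saturates above zero.
* ARTMAP accuracy depends on presentation order; cross-validation and the
  voting mode mitigate but do not remove this.
* Severity distances are comparable only within one fitted model; they are
  not calibrated across cohorts.
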