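# myonet

Quantitative, reproducible analysis of muscle-biopsy cross-sections for
neuromuscular pathology assessment.

Histological evaluation of muscle biopsies — fiber size variation, rounded
atrophic fibers, endomysial fibrosis in muscular dystrophy (MD); grouped
angulated atrophy and fiber-type grouping in neurogenic atrophy (NA) — is
traditionally a qualitative, pathologist-dependent judgment. `myonet`
implements an automated pipeline that turns an immunofluorescence image
(collagen VI in green outlining every fiber, slow myosin in red, fast fibers
dark) into a quantitative severity score:

1. **Segmentation** — fibers are dark valleys of the green channel G. The
   h-minima transform (reconstruction-by-erosion of G + h over G, with
   h = mean(G)/2) suppresses shallow noise minima; regional minima become
   internal markers, ridge lines of their distance transform become external
   markers, and a marker-controlled watershed of the morphological gradient
   |δ(G) − ε(G)| recovers each fiber contour. Fibers are typed slow/fast from
   mean red intensity.
2. **Muscle network** — each fiber is expanded until it meets its neighbors
   (nearest-fiber assignment of every collagen pixel). Touching expanded
   cells define adjacency; the result is a weighted planar graph with one
   node per fiber and edge weights equal to centroid distances. A fiber's
   expanded area A1 over its own area A2 is its local fibrosis index.
3. **Features** — a canonical 82-slot vector per image: 16 geometric
   (mean/sd of size, shape, orientation, and the A1/A2 pair), 8 neighborhood
   (degree statistics overall, per type, per neighbor type), 14 relation
   (each geometric quantity relative to the neighbor mean), and 44 graph
   (strength, clustering, eccentricity, betweenness, path lengths over
   all/slow/fast populations, plus whole-network scalars such as algebraic
   connectivity, s-metric, assortativity, transitivity, modularity).
4. **Discriminant selection** — sequential forward/backward wrapper search
   (SFS/SBS) scored by stratified k-fold cross-validated error of a
   Fuzzy-ARTMAP classifier (complement coding, fuzzy choice function
   T_j = |I ∧ w_j| / (α + |w_j|), vigilance and match tracking).
5. **Severity** — selected features are z-scored and projected on 2–3
   principal components; an image's severity score is the Euclidean distance
   of its projection from the control centroid, validated against grades by
   Pearson correlation. New images are classified by a triple
   (control/MD/NA) and two pairwise comparisons.

Because no clinical images are distributable, the package ships a
first-class synthetic-biopsy generator (`myonet.synthetic`): Voronoi mosaics
on jittered hexagonal lattices with dials for fibrosis band width, fiber
size heterogeneity, corner rounding and fiber-type grouping, rendered in the
three stain channels with full ground truth (label map, types, adjacency, a
scalar severity parameter). Every claim the test suite makes is validated
against this ground truth.

## Worked example

```bash
myonet simulate --preset mixed --n 12 --seed 0 --out cohort
myonet analyze --manifest cohort/manifest.csv --out run --seed 1
```

or directly from Python:

```python
import numpy as np
from myonet import SyntheticSpec, generate_biopsy, analyze_image

img, truth = generate_biopsy(SyntheticSpec(fibrosis=6.0, seed=1))
res = analyze_image(img.rgb, image_id="demo")
print(len(res.fibers), res.features[15], res.features[17])
```

prints

```
49 1.7388335722729737 6.0
```

49 segmented fibers (all 49 ground-truth fibers recovered), a mean A1/A2
fibrosis index of 1.74 (a fibrosis band of 6 px around each fiber; a healthy
mosaic sits near 1.05), and a mean neighbor count of 6.0, the
hexagonal-packing value. On a full control + MD-ramp cohort,
`myonet analyze` writes the feature table, the SFS selection, and a severity
report whose centroid distances grow monotonically with the generator's
severity parameter.

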