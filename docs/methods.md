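# Methods

This note documents the models implemented in `dasypop`, the defaults and
conventions chosen where the underlying methods leave them open, what the
synthetic generator does and does not emulate, and the package's known
limitations.

## Data model and conventions

All stages operate on a co-registered band stack (blue, green, red, NIR,
optional panchromatic) on one working grid. Digital numbers are kept on an
8-bit-like 0–255 scale so that the published rule thresholds (brightness
≥ 136, 256 GLCM gray levels) are meaningful. Grids are indexed (row, col)
with row 0 at the north edge; solar azimuth is measured clockwise from
grid north, and shadows fall along azimuth + 180°. Raster I/O uses plain
TIFF with a JSON sidecar carrying pixel size, origin and solar geometry;
vector outputs are GeoJSON-style JSON. Zero-denominator conventions:
NDVI/NDWI are 0 where both bands vanish; c3 is π/2 where max(R, G) = 0
with B > 0 and 0 on all-zero pixels. These conventions prevent undefined
pixels from propagating.

## PanTex

GLCM contrast of a window equals the mean squared gray-level difference
over co-occurring pixel pairs once the matrix is symmetrised and
normalised; the raster implementation exploits this identity with
integral-image box sums, and the explicit GLCM construction is retained as
an independent slow path used by the tests. Choices the method leaves
open:

* **Displacement set.** Ten vectors of pairwise-distinct direction at
  Chebyshev distance ≤ 2: (0,1), (1,0), (1,1), (1,−1), (0,2), (2,0),
  (2,1), (1,2), (2,−1), (1,−2). The set is closed under 90° rotation up
  to sign, which gives the index an exact rotation-equivariance property
  used as a test.
* **Borders.** Windows are truncated at the image edge rather than padded,
  so no co-occurrences are fabricated.
* **Quantization.** Linear min–max rescale to the configured level count
  (default 256) before pair counting; this makes the index invariant to
  additive brightness shifts.
* Default window size 7 and the built-up threshold 1.45 follow the
  published configuration; window sizes 4/9/14 remain reachable through
  `GlcmConfig` for sensitivity experiments.

## MBI and MSI

White/black top-hats by reconstruction use flat linear structuring
elements at 0°, 45°, 90° and 135°, lengths 2 to 65 in steps of 7 (ten
scales). "Length" counts pixels along the digital line (Chebyshev
normalisation), so a 45° element of length 5 spans five diagonal pixels.
The differential profile uses absolute forward differences — top-hat
profiles are not monotone in general and the index presumes non-negative
aggregation. The printed normalisation D × S is kept although forward
differencing yields S − 1 terms per direction; this scales the index by a
constant (S−1)/S and is absorbed by the decision threshold.

Dilation is implemented as the adjoint of erosion (reflected structuring
element), which makes closing-by-reconstruction the exact dual of
opening-by-reconstruction under image inversion even for even-length
elements; consequently MSI(b) = MBI(max(b) − b) holds to machine precision
and is enforced by tests. Reconstruction uses 8-connected geodesic
propagation.

## Object-based extraction

Proprietary multiresolution segmentation is replaced by thresholding the
chosen index at the rule threshold followed by 8-connected component
labelling; the rule engine accepts any labelled image, so a different
segmentation provider can be plugged in. Feature conventions:

* **Perimeter** is exposed pixel-edge length; **shape index** is
  perimeter / (4√area), which is 1 for solid squares. The alternative
  literal reading (perimeter/√area) would score even a single pixel at 4
  and make the published threshold of 2.6 unsatisfiable.
* **Length/width ratio** comes from the minimum-area rotated bounding box
  of the pixel-corner hull (so 1-pixel-wide objects have width 1, not 0).
* **Rectangular fit** compares the object against a rectangle with the
  bounding box's orientation and aspect, centred on the pixel centroid and
  scaled to the object's area; the score is the fraction of object pixels
  inside it.
* **Hole filling** closes interior holes up to the configured box size
  (default 5×5); it never removes foreground and cannot merge objects.
* **POI refinement** keeps a building iff the nearest point of interest
  within the search radius (default 50 m) is residential. The join rule
  (nearest-within-radius) is a package choice; the source data dictate
  only that POIs discriminate residential from other buildings.

## Shadow heights

The maximum between-class-variance (Otsu) threshold scans all 256
bin-boundary candidates of the sample histogram; ties (which occur when
consecutive bins are empty) are resolved by the mean of the maximising
candidates, with a 1e-9 relative tolerance absorbing float jitter between
algebraically identical partitions. Shadow masks then drop pixels with
NDVI > 0.1 or NDWI > 0.3 and components that are too small
(default < 30 m²) or too elongated. The elongation cut-off defaults to
15: building shadows are at most ~12:1 elongated (wide building, short
shadow) while road fragments run tens of times longer than wide.

Shadow length is measured by grouping component pixels into unit-pixel
scan lines perpendicular to the sun–shadow axis; each line's length is its
pixel count × pixel size, and the component length L is the median over
lines (mean/max are configurable). The median resists merged-shadow tails,
the method's known failure mode in dense blocks. Heights H = L·tan β are
anchored at each component's sun-side pixel and transferred to building
centroids by inverse-distance weighting (power 2); buildings with no
sample within the search radius (default 100 m) fall back to the median
sample height, and a shadow-free scene falls back to a configured default
with a warning. IDW replaces the proprietary curvature-based surface
interpolation used in the original workflow; for point-to-centroid
transfer it is deterministic and dependency-free.

The colour-invariant route computes c3, a 3×3 local variance (boundary
texture), and the same threshold/cleanup chain. How the variance image is
binarised is unspecified in the source method; the same MBCV criterion is
used for consistency.

## Population model

Zone parameters are ratios of survey totals (LA = ΣA/ΣP, AH = Σ(H−RH)/ΣF),
not means of per-sample ratios. Floors BH/AH stay real-valued by default
(rounding is a config flag). The volume-preserving constant C is additive
and uniform per building, matching its position inside the per-building
formula; because an additive constant can push very small buildings
negative, negatives are clamped to zero and the deficit re-spread over
positive buildings (≤ 10 rounds, then proportional rescale), so the census
total is met to < 1e-6 relative error in all cases. The per-zone
correction ε_t is the zone-mean survey residual (the closed-form least
squares solution) and defaults to 0 without surveys; it is applied before
C so the pycnophylactic constraint always holds exactly. Per-class kappa
in the detection summaries is the conditional kappa on each class's actual
margin.

## Synthetic scenes

The generator emulates the statistical structure the pipeline assumes:
axis-aligned bright rooftops (DN 200 in all bands), cast shadows rendered
as the footprint swept along azimuth + 180° by H/tan β (DN 25), background
soil (~DN 70–105 across bands), vegetation with NDVI ≈ 0.6, water with
NDWI ≈ 0.57, elongated bright road strips, and additive Gaussian noise
clipped to 0–255. Defaults mirror the study setting: 2.5 m pixels, solar
altitude 68.68°; azimuth defaults to 180° (due-south sun) since the
original acquisition azimuth is unpublished. Random layouts draw building
short sides of 4–7 px with aspect ratios inside the elongation rule
window, and heights quantised to integer-pixel shadow lengths (2–5 px ≈
12.8–32 m), which makes noiseless recovery well posed. Overlapping
building-plus-shadow regions are rejected so shadow geometry stays
unambiguous; an `allow_overlap` flag reproduces the merged-shadow failure
mode for robustness experiments.

What the generator does **not** emulate: radiometric sensor effects (PSF,
quantisation artefacts, haze), terrain relief and slope-dependent shadow
distortion, non-rectangular building shapes, rooftop heterogeneity, and
shadows cast onto other roofs. Passing recovery tests therefore
demonstrates the correctness of the geometric and statistical machinery,
not performance on real imagery.

## Problem sizes and numerical checks

The test suite verifies each operator against brute-force oracles on small
inputs (pixel-pair enumeration for GLCM contrast, exhaustive 256-candidate
threshold scans, geodesic-dilation fixpoints on ≤ 16×16 grids) and checks
the analytic invariants (index non-negativity and shift invariance,
MSI/MBI duality, height-law monotonicity, pycnophylactic exactness,
RTAE/TAE identities). End-to-end recovery runs use a noiseless 512×512
scene with 20 buildings (count recovered exactly; height errors below one
pixel of shadow length × tan β = 6.4 m; per-unit RTAE < 0.05) and a noise
sweep of 10 seeds × noise sd {0, 4, 8} DN on 192×192 scenes with 6
buildings, whose mean height error increases monotonically with noise.

## Known limitations

* The MBCV threshold assumes a bimodal index histogram; on sparse scenes
  with heavy noise (≥ ~10 DN) the background mode dominates and shadow
  masks degrade quickly. Real urban scenes have much larger shadow
  fractions than the sparse synthetic layouts.
* Shadows shorter than one pixel are undetectable; no sub-pixel recovery
  is attempted.
* The per-class kappa printed for the MBI case-study table is not
  reproducible from its own counts by any standard conditional-kappa
  formula; the package documents its formula and validates against the
  table whose values are internally consistent.
* Heights transfer to buildings by spatial proximity only; in dense
  blocks with merged shadows the assignment is ambiguous by construction.
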