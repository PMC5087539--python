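# dasypop

Fine-scale population estimation from 3D reconstruction of urban
residential buildings in high-resolution satellite imagery.

Census counts are published for large administrative units, but emergency
response, epidemiological modelling and urban planning need to know where
people actually live *inside* those units. `dasypop` implements a
building-level dasymetric approach: it extracts residential building
footprints and heights directly from co-registered panchromatic +
multispectral imagery, converts each building's volume into a population
estimate, and redistributes the census total over buildings while
preserving it exactly.

## The model

The pipeline has three stages.

**Building footprints.** Two morphological/textural indices highlight
built-up structure: *PanTex*, the per-pixel minimum over displacement
vectors *m* of windowed gray-level co-occurrence contrast,

    PanTex(i,j) = min_m  Σ_{a,b} (a − b)² P_{a,b}(i,j; m)

and the *morphological building index* (MBI), the mean over directions *d*
and structuring-element lengths *s* of the differential white
top-hat-by-reconstruction profile of the brightness image *b*,

    MBI = Σ_{d,s} |ΔW_TH(d, s)| / (D × S),   W_TH(d,s) = b − γ_re(d,s).

The index raster is thresholded, split into connected objects, and each
object is screened by conjunctive rules on index level, brightness, NDVI,
length/width ratio, rectangular fit and shape index; point-of-interest
records then isolate residential buildings.

**Heights from shadows.** The *morphological shadow index* (MSI — the black
top-hat dual of the MBI) or a colour-invariant channel
c3 = arctan(B / max(R, G)) locates cast shadows; masks are binarised with a
maximum between-class-variance threshold and cleaned by NDVI/NDWI and
component rules. Scan lines parallel to the sun–shadow axis measure each
shadow's length L, and for solar altitude β the building height is

    H = L · tan β.

**Dasymetric population.** Each building of footprint FS and height BH in
zone *t* (with survey-estimated living area per person LA_t and storey
height AH_t) contributes

    Pop_i = (FS / LA_t) · (BH / AH_t) + C + ε_t,

where ε_t is a least-squares per-zone correction and C is the constant that
makes the per-building total equal the census count — Tobler's
pycnophylactic (volume-preserving) property.

A fully ground-truthed synthetic scene generator renders rooftops, cast
shadows consistent with the solar geometry, vegetation/water/road
distractors and forward-model census totals, so the whole chain is testable
without satellite downloads.

## Worked example

```python
from dasypop import run_synthetic
from dasypop.synthetic import random_scene_spec

spec = random_scene_spec(12, shape=(256, 256), seed=5)
res = run_synthetic(spec, zone_params={z: (25.0, 3.0) for z in range(1, 5)})
print(res["n_buildings_detected"], round(res["height_mae"], 2), round(res["unit_rtae"], 4))
```

prints

```
12 0.52 0.0052
```

— all 12 buildings recovered, mean height error 0.52 m (sub-pixel at 2.5 m
pixels), and a per-unit population RTAE (total absolute error divided by
total census population; 0 is perfect, 2 is complete misallocation) of
0.005. The `examples/` directory contains one short narrative script per
capability (spectral indices, PanTex, MBI/MSI, extraction rules, shadow
heights, the population model, the full pipeline, and the case-study
tables); each prints the numbers it computes and one line on what they
mean. A thin CLI (`dasypop simulate|indices|extract-buildings|
extract-shadows|run-synthetic|reproduce-tables`) wraps the same functions
for shell use.

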