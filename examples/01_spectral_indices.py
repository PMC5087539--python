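"""Spectral indices on a tiny hand-made scene.

Builds a 3-pixel scene containing a bright rooftop, a vegetated pixel and a
water pixel, and prints the derived indices used throughout the pipeline.
"""

import numpy as np

from dasypop import MultispectralScene, SolarGeometry
from dasypop import c3_index, compute_brightness, compute_ndvi, compute_ndwi

#                 roof   vegetation  water
blue = np.array([[200.0,  50.0,  90.0]])
green = np.array([[200.0,  80.0, 110.0]])
red = np.array([[200.0,  45.0,  70.0]])
nir = np.array([[200.0, 180.0,  30.0]])

scene = MultispectralScene(blue=blue, green=green, red=red, nir=nir,
                           pixel_size=2.5, solar=SolarGeometry(68.68, 180.0))

for name, idx in [("brightness", compute_brightness(scene)),
                  ("NDVI", compute_ndvi(scene)),
                  ("NDWI", compute_ndwi(scene)),
                  ("c3", c3_index(scene))]:
    print(f"{name:10s} roof={idx.values[0,0]:7.3f}  veg={idx.values[0,1]:7.3f}  water={idx.values[0,2]:7.3f}")

print()
print("Brightness is the band-wise maximum (the rule base thresholds it at 136);")
print("NDVI > 0.1 flags vegetation, NDWI > 0.3 flags water, and the c3 channel")
print("(arctan of blue over max(red, green), radians) rises in shadowed areas.")
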