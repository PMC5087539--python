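"""PanTex built-up texture index on a synthetic panchromatic band.

Renders a small scene with two buildings and prints the PanTex contrast at
a building corner versus open ground: built-up pixels show high gray-level
co-occurrence contrast in every direction, ground shows none.
"""

import numpy as np

from dasypop import GlcmConfig, pantex_raster, render
from dasypop.synthetic import BuildingSpec, SceneSpec

spec = SceneSpec(shape=(48, 48), buildings=[
    BuildingSpec(20, 10, 6, 12, height_m=19.2),
    BuildingSpec(30, 30, 8, 8, height_m=25.6),
])
scene, truth = render(spec)

cfg = GlcmConfig(levels=64, window_size=7)
ptx = pantex_raster(scene.pan, cfg).values

on_building = ptx[truth.footprint_mask].mean()
on_ground = ptx[~(truth.footprint_mask | truth.shadow_mask)].mean()
print(f"PanTex window {cfg.window_size}, {cfg.levels} gray levels, "
      f"{len(cfg.displacements)} displacement vectors")
print(f"mean PanTex on buildings: {on_building:8.2f}")
print(f"mean PanTex on ground:    {on_ground:8.2f}")
print()
print("The min-over-displacements fusion suppresses linear features that are")
print("high-contrast in only some directions; the classification rule base")
print("labels objects built-up above a PanTex threshold of 1.45.")
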