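"""Full chain on a synthetic scene: indices -> buildings -> heights -> population.

Renders a ground-truthed scene, runs every stage, and scores the recovery:
building count, per-building height error, and per-unit population RTAE
(total absolute error over total census population; 0 = perfect).
"""

from dasypop import run_synthetic
from dasypop.synthetic import random_scene_spec

spec = random_scene_spec(12, shape=(256, 256), seed=5, noise_sd=0.0)
zone_params = {z: (25.0, 3.0) for z in range(1, 5)}  # LA m2/person, AH m/floor

res = run_synthetic(spec, zone_params)

print(f"buildings: {res['n_buildings_detected']} detected of {res['n_buildings_true']}")
print(f"height MAE: {res['height_mae']:.2f} m "
      f"(max {res['height_abs_errors'].max():.2f} m)")
print(f"per-unit population RTAE: {res['unit_rtae']:.4f}")
print(f"detection accuracy at validation points: "
      f"{res['detection']['overall_accuracy']:.3f} "
      f"(kappa {res['detection']['kappa']:.3f})")
print(f"volume constant C: {res['constant_c']:.3f} persons/building")
print()
print("On noiseless scenes the chain recovers the building count exactly and")
print("heights to sub-pixel accuracy; noise degrades recovery gracefully.")
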