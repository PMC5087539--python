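"""Recompute the case-study validation summaries from the packaged tables.

The package ships the published validation tables of the Beijing Chaoyang
case study (574 detection/height validation points, 42 administrative
units) as CSV fixtures; every summary statistic is recomputed from the raw
counts rather than copied.
"""

from dasypop import reproduce_case_study_tables

t = reproduce_case_study_tables()

for key in ("mbi", "pantex"):
    d = t[f"detection_{key}"]
    print(f"{key.upper():6s} detection: overall accuracy {d['overall_accuracy']:.2f}, "
          f"kappa {d['kappa']:.2f}")

print(f"\nheight absolute error < 2.5 m: "
      f"MSI {t['height_msi']['percentages'][0]:.2f}% vs "
      f"CIIT {t['height_ciit']['percentages'][0]:.2f}% of 574 points")

p = t["population"]
print(f"\npopulation over {p['n_units']} administrative units:")
print(f"  mean |RE| {p['mean_abs_re']:.2f}%   RTAE {p['rtae']:.3f}")
print(f"  units with |RE| < 10%: {p['counts_below'][10.0]}, < 30%: {p['counts_below'][30.0]}")
print(f"  model total {p['model_total']:,.3f} vs census {p['statistic_total']:,.0f}")
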