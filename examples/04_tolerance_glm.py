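"""Fitness tolerance: Poisson GLM of total seed number.

Tolerance is the slope of fitness across environments: the difference in
mean seed number between defoliated and control plants of an ecotype.
Positive slope = overtolerance, ~0 = complete tolerance.
"""

import defol

presets = [defol.make_preset("PN"), defol.make_preset("SD")]
counts = defol.simulate_seed_counts(presets, n_per_cell=1000, seed=1)
fit = defol.fit_seed_glm(counts)

print("likelihood-ratio tests (hierarchical drops):")
for term, (chi2, df, p) in fit.lr_tests.items():
    print(f"  {term:18s} chi2 = {chi2:9.2f}  df = {df}  p = {p:.3g}")

print("\nfitted cell means and tolerance slopes:")
for eco in fit.ecotypes:
    print(f"  {eco}: control {fit.cell_means[(eco, 'control')]:6.1f}  "
          f"defoliated {fit.cell_means[(eco, 'defoliated')]:6.1f}  "
          f"slope {fit.slopes[eco]:+7.1f} seeds "
          f"({fit.percent_change[eco]:+5.1f} %)")

contrasts = defol.pairwise_group_contrasts(fit)
letters = contrasts.attrs["letters"]
print("\nHolm-adjusted pairwise contrasts (shared letter = no difference):")
for cell, letter in sorted(letters.items()):
    print(f"  {cell:14s} {letter}")
print("\nSD is overtolerant (defoliation raises seed set ~23 %); PN is "
      "completely tolerant (no fitness difference).")
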