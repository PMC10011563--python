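"""Preprocess an assemblage and compare chemometric ratios between groups.

The chain truncates each spectrum to 3000-1400 cm^-1, cuts the
2700-1760 cm^-1 interval (atmospheric CO2 / diamond ATR / high silica
overtones), resamples to a 2 cm^-1 grid, removes the rubberband (lower
convex hull) baseline per segment and min-max normalizes so the dominant
~1615 cm^-1 silica band maps to 1.  Ratios are then read off band maxima
and the two domains compared with two-sided Mann-Whitney U tests.
"""

import chertspec as cs

sset, _ = cs.generate_assemblage(cs.AssemblageConfig(seed=42))
matrix, segs, reports = cs.preprocess_pipeline(sset)

anchored = sum(r["max_at_anchor"] for r in reports)
print(f"feature matrix: {matrix.shape[0]} specimens x {matrix.shape[1]} "
      f"wavenumber points; {anchored}/{len(reports)} spectra have their "
      f"global maximum at the 1615 cm^-1 silica band (normalization anchor)")

ratios = cs.ratio_table(segs)
print("\ngroup means of the chemometric ratios:")
print(ratios.groupby("group").mean(numeric_only=True).round(3))

print("\ntwo-sided Mann-Whitney U tests (prokaryotes vs eukaryotes):")
comps = cs.compare_all_ratios(ratios)
for _, row in comps.iterrows():
    print(f"  {row['ratio']:>10}: U={row['U']:5.0f}  p={row['p_value']:.4f}  "
          f"means {row['mean1']:.3f} (prok) vs {row['mean2']:.3f} (euk)")
print("\nA small p for the carbonyl and N-moiety ratios but not for R3/2 "
      "mirrors how sugar/protein fossilization products, not aliphatic "
      "chain branching, separate the domains.")
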