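"""Fold-change enrichment of lipid species near a pore.

Simulates three replicate near-pore count series in which one species
(PC 38:4) is given a 2-fold preference for the pore vicinity, then runs
the full decorrelation-aware analysis: autocorrelation-time estimation,
segmentation, fold changes against the bulk leaflet composition, and
Bonferroni-corrected one-sample t-tests.
"""

from lipopore.enrichment import analyze_enrichment
from lipopore.synth import gen_count_series

counts, truth = gen_count_series(weights={"PC 38:4": 2.0}, seed=1)
results, info = analyze_enrichment(counts, truth["bulk_fraction"])

print(f"Largest integrated autocorrelation time: "
      f"{info['tau_max_ns']:.1f} ns -> segments of "
      f"{info['segment_frames']} frames, "
      f"{min(info['n_segments'].values())} per replicate")
print(f"(generator truth: tau_int = {truth['tau_int']:.1f} ns)\n")

cols = ["mean_fc", "ci_low", "ci_high", "p_adj"]
print(results[cols].round(3).to_string())
print("\nFold change = near-pore amount fraction / bulk leaflet fraction;"
      "\nCI is family-wise 99%, p Bonferroni-corrected over "
      f"{results['m'].iloc[0]} species.")
enriched = results[results["p_adj"] < 0.01].index.tolist()
print(f"Significant at adjusted p < 0.01: {enriched} "
      f"(true enriched FC = {truth['fold_change']['PC 38:4']:.3f})")
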