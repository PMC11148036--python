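# lipopore

Analysis tools for studying how lipid composition — in particular acyl-chain
unsaturation — shapes the formation and properties of toroidal membrane
pores such as the BAX/BAK apoptotic pore. The package covers the
computational stages of such a study end to end:

- **Lipidomics** (`lipopore.lipidomics`): shotgun-MS quantification of
  glycerophospholipid species against per-class internal standards
  (amount = area/area_IS x pmol_IS / mg protein), replicate-paired
  apoptotic-vs-control fold changes, saturated/mono/polyunsaturated
  profiles, paired t-tests.
- **Membrane composition** (`lipopore.membrane`): turning a measured
  composition into an asymmetric two-leaflet coarse-grained build recipe —
  headgroup classes split between cytoplasmic and intermembrane-space
  leaflets (PS 30/70, PI 30/70, PE 77/23, PC 55/45, PG 50/50), integer
  counts by largest-remainder rounding with a minimum of 5 lipids per
  retained species per leaflet, and tension-free leaflet area matching.
- **Pore geometry** (`lipopore.pore`): the membrane-spanning-cylinder pore
  coordinate ξ — the fraction of 40 axial slices (8 nm cylinder, 0.2 nm
  slices, 3 nm diameter) occupied by polar beads, with continuous slice
  occupancy δ_s = 1 − exp(−c_s/ζ), ζ = 0.2; the cylindrical harmonically
  repulsive restraint (R = 3 nm, k = 500 kJ/mol/nm²) on first tail beads;
  pore-associated lipid selection within a 4 nm vicinity cylinder under the
  xy minimum-image convention.
- **Enrichment statistics** (`lipopore.enrichment`): fold-change enrichment
  FC(s) = (near-pore fraction of s)/(leaflet fraction of s) computed on
  time-uncorrelated segments (segment length = the largest integrated
  autocorrelation time over species, same length discarded from the start
  of each replicate), tested against 1 with two-tailed one-sample t-tests,
  Bonferroni correction and family-wise 99% confidence intervals.
- **Free-energy profiles** (`lipopore.wham`): WHAM reconstruction of the
  potential of mean force G(ξ) = −kT ln P(ξ) from harmonic umbrella
  windows, iterating P(ξ_b) = Σᵢ nᵢ(ξ_b) / Σᵢ Nᵢ exp[(Fᵢ − wᵢ(ξ_b))/kT]
  to self-consistency, with autocorrelation-aware block-bootstrap errors
  and pore-opening ΔG / between-condition ΔΔG readouts.
- **Vesicle assays** (`lipopore.vesicles`): LUV dye release
  %R = 100(Ff − Fi)/(Fm − Fi); GUV degree of filling
  DF = (lumen − bg)/(exterior − bg); permeabilized fractions, all-or-none
  vs graded mechanism classification, two-dye pore stability, 12 vs 104 kDa
  size selectivity, and cell-death AUC.
- **Synthetic data** (`lipopore.synth`): seeded generators with exact
  ground truth for every stage — toy bead bilayers with or without an open
  pore and with controllable per-species vicinity enrichment, AR(1) series,
  Metropolis samples from analytic landscapes under umbrella biases, GUV
  populations, paired lipidomics tables.

Coordinate interoperability (GRO/PDB/XTC plus a YAML bead map) is in
`lipopore.io`. The package is a library: import it, or run the narrative
scripts in `examples/`.

## Worked example

Reconstructing a free-energy profile from umbrella sampling
(`examples/pmf_wham.py`):

```sh
$ python examples/pmf_wham.py
Sampled 15 windows x 20000 points (Metropolis acceptance 0.61)
WHAM converged in 175 iterations
Recovered barrier G(0.5) - G(0.02) = 19.89 kJ/mol (truth 20.0)
Profile RMSE vs analytic landscape over xi in [0.1, 0.9]: 0.11 kJ/mol; mean bootstrap error 0.09 kJ/mol
```

Fifteen harmonic windows are sampled by Metropolis Monte Carlo from a known
20 kJ/mol cosine landscape along the pore coordinate; WHAM recombines the
biased histograms into the unbiased profile. The recovered barrier (19.89
kJ/mol) and the 0.11 kJ/mol RMSE against the analytic curve show the
reconstruction is accurate to well under thermal energy (kT ≈ 2.49 kJ/mol
at 300 K).

Enrichment analysis (`examples/enrichment_analysis.py`) on a trajectory
where one species has a 2-fold preference for the pore vicinity:

```
         mean_fc  ci_low  ci_high  p_adj
PC 38:4    1.826   1.744    1.909  0.000
...
Significant at adjusted p < 0.01: [...'PC 38:4'...] (true enriched FC = 1.818)
```

The enriched species' fold change is recovered within its 99% confidence
interval; the complementary mild depletion of the other species (FC ≈ 0.9)
is the arithmetic consequence of near-pore fractions summing to one.

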