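# Methods

This note documents the models, estimators and numerical choices behind
each module, what the synthetic-data generators do and do not emulate, and
the design decisions taken where the underlying procedures left room.

## Lipidomics quantification

Shotgun lipidomics resolves glycerophospholipids at sum composition
(class, total acyl carbons, total double bonds; e.g. "PC 34:1"). One
internal standard per headgroup class converts peak areas to absolute
amounts,

    amount(s) = area(s) / area(IS_class) * pmol(IS_class) / protein_mg,

in pmol per mg protein. Amounts are standardized to pmol/mg internally;
nmol/mg input is accepted with a unit tag and scaled. Fold changes are
replicate-paired ratios, summarized as the mean over replicates; cells
with a zero control amount are flagged undefined and excluded from the
mean (with a warning count) rather than propagated as infinities.
Species with zero amount in every replicate of both conditions are
dropped from fold-change summaries. Saturation classes key on the total
double-bond count of the label (0 saturated, 1 monounsaturated, ≥2
polyunsaturated); sn-position resolution is not available at shotgun
resolution, so a species like 16:0/20:4 appears and is classified as
36:4. The paired t-test operates on per-class replicate totals:
t = d̄/(s_d/√n), df = n−1, two-tailed; zero-variance differences return an
undefined flag rather than an infinite statistic.

## Membrane composition

The composer converts whole-membrane species fractions into an integer,
asymmetric, tension-free two-leaflet recipe in three steps.

1. *Leaflet split.* Each headgroup class c with membrane fraction f(c)
   contributes f(c)·a(c) to the cytoplasmic leaflet and f(c)·(1−a(c)) to
   the IMS leaflet, with default asymmetry fractions a = 0.30 (PS), 0.30
   (PI), 0.77 (PE), 0.55 (PC), 0.50 (PG). The ratio notation in the
   literature does not fix which leaflet is listed first, so the reading
   is controlled by an explicit `flip` flag (default: first number =
   cytoplasmic). Classes without a tabulated asymmetry (e.g. PA) default
   to 50/50 with a warning; a strict mode raises instead.
2. *Integer allocation.* Fractions become counts by largest-remainder
   (Hamilton) apportionment, which sums exactly to the leaflet total;
   remainder ties break by descending fraction then label. Species
   landing below 5 copies per leaflet are merged into the same-class
   species with the nearest tail composition (minimize |Δcarbons|, then
   |Δdouble bonds|, then label) and the remainder re-rounded until all
   retained species have ≥5; a class that cannot reach 5 and has no
   partner is an error.
3. *Area matching.* With per-leaflet areas per lipid (APLs) supplied by
   the user — they come from separate symmetric simulations and are
   inputs here, not computed — the leaflet with the larger expected area
   N·APL is trimmed to round(N_other·APL_other/APL_self) lipids,
   distributed proportionally across species by largest remainder, so the
   juxtaposed leaflets match within one lipid's area. Matched leaflets
   pass through unchanged (idempotence).

Hydration is recorded as 25 waters per lipid and ions as the pairs needed
for 0.15 M relative to water (55.5 M) plus cations neutralizing the net
lipid charge (PS/PI/PG/PA −1, CL −2); only counts are recorded — solvent
placement is out of scope. A 20 × 20 nm box at APL 0.708 nm² yields
565 lipids per leaflet, 1130 total.

## Pore coordinate and restraint

The pore coordinate ξ measures how far a membrane-spanning polar channel
has formed: a cylinder of diameter 3.0 nm and height 8 nm, centered on the
membrane midplane and the pore axis, is divided into 40 slices of 0.2 nm.
For slice s holding c_s polar beads (headgroups, water, ions, by bead
center, radial membership a hard cutoff under the xy minimum-image
convention),

    δ_s = 1 − exp(−c_s / ζ),   ξ = (1/40) Σ_s δ_s,

with ζ = 0.2, so a single bead already gives δ ≈ 0.993 — a smooth,
saturating stand-in for near-binary slice counting. The exact switching
function of the originally published coordinate may differ in detail;
this form preserves its range, monotonicity and saturation behaviour and
is clearly flagged as this package's choice. The midplane proxy is the
mean z of head beads; z is non-periodic inside the cylinder.

The pore-opening restraint is harmonically repulsive on first tail beads:
U = k/2 (R − r)² for radial distance r < R (default R = 3 nm,
k = 500 kJ/mol/nm²), zero outside, force k(R − r) radially outward. It is
a scoring/validation device here; integrating dynamics against it is not
in scope.

Pore-associated lipids are those with any bead within the vicinity
cylinder. The "4 nm cylindrical zone" is interpreted as a **radius** (it
must exceed the 3 nm restraint radius to capture rim lipids);
the parameter is configurable for the diameter reading.

## Enrichment statistics

Counts of each species among pore-associated lipids, per frame and
leaflet, are reduced to per-frame amount fractions (frames with an empty
vicinity give NaN fractions and are excluded from segment means, with a
warning count; their count rows are kept as zeros). The integrated
autocorrelation time of each species' count series,

    τ_int = Δt (1 + 2 Σ_{k=1..W} ρ_k),

uses the initial-positive-sequence window W (sum to the first negative
autocorrelation). The largest τ_int over species and replicates sets the
segment length; the same length is discarded from the start of each
replicate to decorrelate from the starting configuration, and the
remainder is cut into contiguous segments whose mean fraction vectors are
the analysis units. Segment length equals τ_max itself (not a multiple):
this reproduces segment counts consistent with the reference workflow and
is configurable in effect through the series length.

Fold change per segment is FC(s) = fraction_near(s)/fraction_leaflet(s),
referenced to the **per-leaflet** composition (the cytoplasmic and IMS
sides are analyzed separately). Because near-pore fractions are a
probability distribution, Σ_s f_leaflet(s)·FC(s) = 1 exactly on every
segment — a useful internal consistency check. The default test
population is the pooled segment means across replicates (one-sample
two-tailed t vs 1); a per-replicate-average mode (n = replicates) exists
because summary plots often show replicate means. p-values are Bonferroni
adjusted over m comparisons (default: the number of targets tested) and
confidence intervals are family-wise 99% (per-test level 1 − 0.01/m).
FCs are summarized on the linear scale; a log-scale test can be had by
transforming the segment FCs before testing.

## WHAM

Umbrella windows are harmonic, w_i(ξ) = k_i/2 (ξ − c_i)² (+ an optional
constant offset, which provably cancels). The self-consistent equations

    P(ξ_b) = Σ_i n_i(ξ_b) / Σ_i N_i exp[(F_i − w_i(ξ_b))/kT]
    F_i    = −kT ln Σ_b P(ξ_b) exp(−w_i(ξ_b)/kT)

are iterated with the first window's F fixed as gauge until
max_i |ΔF_i| < 10⁻⁶ kJ/mol (default; max 10⁵ iterations — typically a few
hundred suffice). Defaults: 200 bins over [0, 1]; bins never visited by
any window are masked (NaN), not extrapolated; temperature 300 K with
k_B = 0.0083145 kJ/mol/K, kT = 2.494 kJ/mol. Before solving, the
window-overlap graph (windows sharing occupied bins) must be connected;
a gap raises an error naming the disconnected windows. Errors come from a
Monte-Carlo circular block bootstrap: each window's samples are resampled
in blocks of its own integrated autocorrelation time (reusing the
enrichment estimator), the full solve repeated, and the per-bin standard
deviation reported. Profile comparisons (ΔG of pore opening, ΔΔG between
conditions) are taken between stated ξ values and are invariant to
additive offsets; each profile is min-shifted at its flat-membrane basin.

## Vesicle assays

LUV release is normalized between the liposome-only baseline Fi and the
detergent maximum Fm: %R = 100(Ff − Fi)/(Fm − Fi), affine-invariant in
the raw fluorescence; spontaneous release is treated as negligible (no
drift correction by default). Endpoint values interpolate linearly
between flanking time points. GUV degree of filling is
DF = (lumen − bg)/(exterior − bg), clamped to [0, 1] with a flag rather
than rejected. A vesicle counts as permeabilized at DF ≥ θ with θ = 0.5
by default; the detector software cutoffs used in practice are not
standardized, so a θ-sensitivity helper reports the fraction across
θ ∈ {0.3…0.7}. The mechanism call is distributional: the population is
all-or-none (bimodal empty/full) when fewer than 10% of vesicles fall in
the intermediate band DF ∈ (0.2, 0.8), graded otherwise; band and cutoff
are parameters chosen to separate clearly bimodal from unimodal-central
populations, and at n = 50 vesicles the classifier recovers the
generating mechanism in ≥95% of simulations. Pore stability is the
conditional fraction P(dye2 filled | dye1 filled) with the joint 2×2
counts; size selectivity partitions vesicles into impermeable /
size-limited (small marker in, large out) / large-pore, with large-only
entry flagged anomalous. Cell-death kinetics are summarized by the
trapezoidal AUC over the observed window.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of (parameters, seed) on
`numpy.random.default_rng`; no global state. Each returns its ground
truth (weights, stationary fold changes, τ_int, the analytic landscape,
the mechanism, the shift) alongside the data.

*Membrane/enrichment.* Lipids are 3-bead stacks (head at ±2 nm from the
midplane, two tail beads toward it — deliberately not physical; the
geometry exists to exercise selections and statistics). Each lipid
carries a two-state near/far Markov chain with stationary near
probability q_s = clip(p₀ w_s, 0.95), p₀ = 0.125 (the area fraction of a
4 nm vicinity cylinder in a 20 × 20 nm patch) and persistence φ giving
indicator autocorrelation φ^k, hence τ_int = Δt(1+φ)/(1−φ); default
φ = 0.6 (τ_int = 4Δt). Near lipids are placed in a radial band inside the
vicinity cylinder, far lipids outside it with a margin, so geometric
association is exact and the stationary near-pore composition — and thus
every fold change — is known in closed form. An open pore adds a static
polar scaffold: water beads along the channel and rim headgroups, driving
ξ ≈ 0.99, versus ξ ≈ 0.5 for the intact bilayer (bulk water above and
below the membrane inside the cylinder). The count-series fast path
(`gen_count_series`) runs the identical state machine without bead
placement and is used for the repeated-simulation calibration suites; its
defaults (150 lipids per leaflet over 9 species, 3 replicates, 1000
frames) are sized so every replicate yields at least 43 decorrelated
segments even when τ is overestimated from data, matching
triplicate-with-≥43-segments sampling. What this generator does **not**
emulate: continuous lateral diffusion, lipid flip-flop, pore shape
fluctuations, correlated motion between lipids, or any force-field
energetics — conclusions from passing tests are about the estimators and
geometry, not about membrane physics.

*Umbrella sampling.* Per window, Metropolis MC targets
exp(−[G(ξ) + w_i(ξ)]/kT) on [0, 1] (out-of-range proposals rejected),
with Gaussian steps of 0.08, 2000-step burn-in and a thinning interval of
5 recorded states to reduce chain autocorrelation; acceptance outside
[0.1, 0.9] attaches a warning suggesting a step change. The cosine
landscape G(ξ) = B[1 − cos 2πξ]/2 provides an analytic truth with barrier
B at ξ = 0.5. With 15 windows of stiffness 400 kJ/mol and 2×10⁴ samples
each, WHAM recovers a 20 kJ/mol barrier within a few tenths of kJ/mol.

*Vesicles.* All-or-none populations draw DF from
p·Beta(20,1) + (1−p)·Beta(1,20); graded from Beta(5,5). A second dye
fills dye1-filled vesicles with probability equal to the stability
parameter; size-limited mode draws the large-marker DF from the empty
component. Intensities are emitted so DF inverts exactly.

*Lipidomics.* Twenty species across PC/PE/PI/PS/PG with double bonds in
{0, 1, 2, 4, 6}; apoptotic amounts multiply polyunsaturated species by
(1 + shift) and saturated by 1/(1 + shift); lognormal replicate noise
(default σ = 0.15) over 4 replicates.

## Numerical choices and edge cases

- Largest-remainder rounding everywhere an integer allocation is needed;
  documented tie-breaks make results deterministic.
- Autocorrelation via FFT; constant series are an explicit error (zero
  variance), series under 50 points are refused.
- τ_int floored at Δt (a series cannot decorrelate faster than its
  sampling interval).
- WHAM bins with zero total counts are masked; interpolation refuses ξ
  outside the visited support.
- Degenerate statistics (zero-variance differences or segment FCs) return
  undefined flags, never infinities.
- Empty configurations give ξ = 0 with a warning; empty vicinity frames
  are zeros in count tables and NaN in fraction space.

## Known limitations

- The continuous slice-occupancy form is a documented stand-in; results
  depending on the exact switching function of the original coordinate
  implementation may differ quantitatively near ξ extremes.
- The enrichment t-test assumes segment means are approximately
  independent and normal; segments of length τ_int retain some residual
  correlation, which mildly understates variance. The null-calibration
  suite bounds the practical effect (observed family-wise flag rate well
  under the nominal budget).
- WHAM here is the standard binned estimator; no MBAR-style binless
  generalization, 2D profiles, or replica exchange.
- GUV metrics operate on per-vesicle intensity tables; image segmentation
  is upstream and out of scope.
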