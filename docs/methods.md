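# Methods

This note documents the measurement model the package implements, the
choices made where the experimental protocol leaves the analysis open, what
the synthetic generator does and does not emulate, and the numerical
policies.

## Measurement model

**¹⁴C carbon budget.** The pulse supplies a known activity A_sup (default
1.1 MBq) of ¹⁴CO₂ to a sealed chamber. For any pool (plant tissue digest,
labelled-core digest, KOH respiration trap) the label proportion
P_r = A_pool / A_sup times the chamber carbon mass m_c gives the total
(¹²C + ¹⁴C) carbon routed into that pool, because the labelled and
unlabelled CO₂ are fixed in proportion. m_c comes from the ideal gas law
with the CO₂ volume taken as chamber volume × treatment mixing ratio
(440 × 10⁻⁶ or 1500 × 10⁻⁶). A configuration switch
(`volume_interpretation='co2_volume'`) instead treats the configured volume
as pure CO₂, for designs that meter CO₂ directly; the mixing-ratio reading
is the default because 0.003 m³ of pure CO₂ in a 3-litre plant chamber is
physically implausible. Defaults T = 288.15 K (15 °C day temperature) and
P = 101.325 kPa, both configurable; R = 8.314 J K⁻¹ mol⁻¹,
M(CO₂) = 44.01 g mol⁻¹ and a carbon mass fraction of 0.27292, both of which
the test suite re-derives from standard atomic masses.

Whole-pool activities are reconstructed from counted aliquots:
plant digests scale by the digest dilution factor (10 ml digest / 2 ml
counted = 5) and the dry-mass/subsample ratio; core digests represent the
whole core and scale by the dilution factor only; KOH traps scale each 2-h
interval by the trap/aliquot ratio (2 ml / 1 ml) and sum over the 6-h
incubation. Background DPM is subtracted with a floor at zero. No quench or
counting-efficiency correction is applied, and ¹⁴C decay over the ≤ 24 h
assay is ignored (half-life 5730 yr, error < 10⁻⁷).

**Total carbon fixed** is the sum of the plant-tissue, labelled-core and
respired pools. The core pool is included because carbon the plant exported
to the fungus was still fixed by the plant; the chamber residual is
excluded because it never was. Counting respired recovery is the default
(`include_respired=True`) and the policy is recorded in the flux table's
metadata.

**³³P.** Counts → activity (÷60) → decay-corrected to the labelling date
(× 2^(t/25.38 d); ON by default over the 21-d chase and reported in
metadata — the alternative, quantifying at harvest, is a pure rescaling) →
mmol via the source specific activity → mass via M_wt = 30.974 mg mmol⁻¹
and the dilution factor. The source specific activity has no safe default
and must be supplied in the design; the synthetic scenario uses
10⁸ Bq mmol⁻¹, a synthetic choice. The dilution factor defaults to each
sample's digest_total/counted_aliquot ratio; a per-campaign override exists
for protocols with additional dilution steps.

**¹⁵N.** Atom-percent excess over background times the tissue nitrogen pool
(%N × dry mass). Background is the mean atom % of each species' unlabelled
control pots, falling back to natural abundance (0.3663 atom %) with a
warning when no controls exist. Negative excess (noise on unenriched
tissue) clamps to zero with a warning; this imposes a small positive floor
bias on near-zero ¹⁵N estimates — relevant only for rotated-core pots whose
leak-derived enrichment is comparable to IRMS precision.

**Differencing.** Hyphal transfer is estimated at treatment-cell level:
mean(static pots) − mean(rotated pots), SE by quadrature of the two SEMs
(pots are not paired in this design; per-pot pairing would need declared
pairs). Negative nets are stored as-is with a flag — diffusion exceeding
apparent transport is informative — but are clamped to zero when used in
efficiency ratios. Efficiency is computed per cell from the net means, not
as a mean of per-pot ratios, matching the error structure of cell-level
reporting; per-pot gross ratios are also emitted for the factorial ANOVA.

## Statistics

Two-way factorial ANOVA (species × CO₂) with Type II sums of squares,
fitted by OLS via statsmodels. Type II was chosen because realized
replicate numbers in pot experiments are routinely unbalanced (lost pots),
Type II coincides with the sequential decomposition on balanced data, and
it matches the "adjusted SS" default of the classic lab statistics
packages. Responses measuring fungal transfer are analysed over static pots
only — rotated pots estimate the diffusion control, not the biological
response; `anova_table(..., pots='all')` overrides this. A response with
zero residual variance is flagged degenerate (terms report F = 0, p = 1
when they explain nothing, F = ∞, p = 0 for exact structural differences).
No response transformation is applied by default.

Post hoc comparisons use the studentized range with the Tukey–Kramer
harmonic correction for unequal n, with quantiles from
`scipy.stats.studentized_range` (numerical accuracy well below 10⁻⁶).
The compact letter display uses the insert-and-absorb algorithm: start with
one letter spanning all groups, split it on each significant pair, absorb
subset letters, and label letters in order of their lowest group mean —
which makes the display independent of group input order. The test suite
verifies the display encodes exactly the brute-force pairwise decisions.

## Synthetic generator

The generator is the package's validation instrument: it forward-simulates
every measured table so that, with noise off, the pipeline is the exact
inverse of the measurement model (verified to < 10⁻⁹ relative error).

Per pot, the fixed carbon splits into tissue, core, respired and chamber
residual fractions that sum to one, so label conservation holds identically.
The diffusion leak is a scalar: static compartments receive the hyphal
quantity × (1 + leak), rotated ones × leak, which makes cell-mean
differencing exactly unbiased for the hyphal quantity. Noise sources:

- **Poisson counting noise** on expected counts accumulated over a 5-min
  count time (physical for decay; CVs of order 0.1–2% at the simulated
  activities);
- **Gaussian IRMS noise** on atom % ¹⁵N (default SD 0.0005 atom %,
  a typical continuous-flow IRMS precision);
- **between-pot biological variability**: mean-one lognormal multipliers
  (default CV 0.15) on fixation, allocation and nutrient delivery. This is
  deliberately included beyond instrument noise: replicate pots of
  wild-collected plants differ in size and colonization, and without it
  within-cell variance would be implausibly dominated by counting error.

Below-ground ¹⁴C kinetics follow a gamma-shaped pulse with mode at the
configured peak time (default 17 h, the design's harvest trigger), sampled
on the 2-h grid; any unimodal shape peaking there would serve, and the
curve is diagnostic, not part of the carbon budget. Dry masses
(0.2–0.4 g), subsample masses (10–30 mg) and %N (1.5–2.5%) are drawn
uniformly per pot. All draws flow from one `numpy` generator seeded per
call; no global state.

The canned scenario (`scenario_liverwort_co2`) encodes the qualitative
response pattern of interest — absolute carbon allocation rising at
1500 ppm CO₂ for both hosts, percentage allocation rising only for the
Treubia-like host, nutrient delivery flat or declining, hence
non-increasing exchange efficiency at high CO₂ — with magnitudes
(fixation 2–5.5 × 10⁻⁴ g, allocation 4–10%, deliveries 250–500 ng)
invented for testability. What passing tests show is that the *pipeline*
is correct and the *design* (differencing, factorial ANOVA) behaves as
claimed under this noise model; they do not validate the biological
magnitudes, quench/efficiency behaviour of real scintillation counters,
IRMS drift, or spatial soil heterogeneity, none of which are modelled.

## Problem sizes and numerical policies

Monte-Carlo checks use 200 replicate campaigns (label conservation,
differencing validity), 1000 null simulations for ANOVA type-I calibration,
and 100 replicates for the scenario pattern — sizes at which Monte-Carlo
SEs are a few per mill of the quantities checked. Degenerate inputs are
handled explicitly: all-zero gas curves yield NA peak times with a warning;
zero total fixed carbon yields NA allocation; nonpositive net carbon yields
NA efficiency; label proportions above 1 clamp with a warning (they
indicate dilution-factor errors). Ties in peak detection break to the
earliest sampling time. Internal units are SI throughout (g, Bq, m³, K,
kPa); ng and mg appear only in reporting columns, preventing silent 10³
errors where protocol constants mix mg, ng and m³.

## Known limitations

- The ¹⁵N clamping floor biases near-zero estimates slightly upward (see
  above); net deliveries well above IRMS noise are unaffected.
- Missing pots are tolerated everywhere downstream, but a cell with no
  static or no rotated pot has undefined net transfer and raises.
- The diffusion leak is a scalar fraction, not a transport model; no
  isotope fractionation, IRMS drift correction, or photosynthesis kinetics
  are modelled.
- Printed F-ratio tables from historical analyses of this design are not
  reproduction targets: per-pot raw data and realized replicate numbers
  are not recoverable from summary tables.
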