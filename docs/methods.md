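# Methods

## Models and assumptions

**Whole-cell kinetics.** Rates are apparent, whole-cell quantities:
Vmax(app) is a relative kcat per mg total cell protein, and Km(app) folds in
transport and cell-envelope effects as well as enzyme affinity. Substrate
inhibition is modelled with the Haldane form
v = Vmax·S/(Km + S + S²/Ki), where Ki is the concentration that halves the
apparent maximum rate. Setting dv/dS = 0 gives the analytic optimum
S_opt = √(Km·Ki), v_opt = Vmax/(1 + 2√(Km/Ki)); Ki → ∞ recovers
Michaelis–Menten. Catalytic efficiency is Vmax/Km, the S → 0 slope of both
laws. Specific affinity a°s is implemented as Vmax/Km on the same
protein-normalised scale and the affinity constant as K_A = 1/Km — the
limiting-slope and inverse-half-saturation definitions of the
substrate-affinity framework. No thermodynamic (Arrhenius/Eyring) model of
Vmax versus temperature is imposed: parameters are empirical per temperature,
with optional linear interpolation between measured temperatures.

**Rate estimation.** A vial's oxidation rate is the OLS slope of its NO2⁻
concentration series (accumulation for NH3 oxidizers, disappearance —
sign-flipped — for NOB), converted to a whole-cell rate by
slope (µM h⁻¹) × vial volume (L) / protein (mg). The default window uses all
sampled points with r² reported; a `first_2h` window is available. Where
substrate depletes appreciably within the window (low S₀ relative to the
biomass load), the trace is convex and the slope *underestimates* the
instantaneous initial rate; this bias is inherent to progress-curve designs
and is reported, not silently corrected. Slopes whose sign contradicts the
guild convention (noise at near-zero activity) are clamped to zero with a
logged warning, because the downstream fits assume v ≥ 0.

**NH3/NH4⁺ speciation.** fraction(NH3) = 1/(1 + 10^(pKa(T) − pH)) with the
Emerson-type relation pKa(T) = A + B/T_K, A = 0.09018, B = 2729.92 K —
standard dilute-solution coefficients, both configurable. Ionic-strength and
carbonate effects are not modelled. Conversions of Km (or Ki) between the
total and free-NH3 bases multiply or divide by the fraction and round-trip
exactly.

**Soil forward model.** Marker copies g⁻¹ ÷ copies genome⁻¹ → cells g⁻¹
(all copies assumed to come from active cells); × protein cell⁻¹ (fg,
optionally derived as cell volume × a protein-density coefficient) →
mg protein g soil⁻¹. Substrate pools are assumed fully dissolved in the
gravimetric water: µmol g⁻¹ ÷ (mL g⁻¹) × 1000 → µM, with no sorption
correction. The amended NH4⁺ concentration uses the amendment pool alone.
Assumed NO2⁻ for NOB predictions: without amendment, the value if all native
NH4⁺ were oxidized; with amendment, the measured per-temperature accumulated
NO2⁻, or the assay detection limit (2 µM) when none accumulated — a branch
that is continuous at the limit. Each organism is evaluated as if it made up
its guild's entire population, so predictions are per-organism potentials,
linear in gene copies and in protein per cell. Two structural rules restrict
the Haldane law: no substrate inhibition of NH3 oxidation is applied in
unamended incubations (concentrations are far below any measured Ki), and
Haldane is dropped for NOB whenever the assumed NO2⁻ sits more than two
orders of magnitude below Ki (ratio < 1e-2, configurable), where the
inhibition term is numerically irrelevant.

**Guild partitioning.** With the 24-h accumulations of NO2⁻ and NO2⁻+NO3⁻
under none/+octyne/+acetylene treatments: total = none − acetylene,
AOA = octyne − acetylene, AOB = total − AOA, and
NOB = total − (NO2⁻ accumulation rate), all divided by 24 h. The default
differences matched replicate triples and then averages (treatments were
applied to parallel bottles); an average-then-difference mode exists.
Negative differences — assay noise around zero activity — are clamped to
zero, each clamp logged.

**Comparison.** Observed guild rates are regressed on predicted rates by
OLS; R², the two-sided slope p-value, slope and intercept are reported. R²
is symmetric in the two series and invariant to affine rescaling;
zero-variance predictions make the regression undefined and are flagged
rather than raised.

## Fitting: numerical choices

- Loss: unweighted least squares on rates (optional 1/v weighting). With
  1/v weighting the reported RSS and AIC are on the weighted scale, matching
  the minimised objective.
- Positivity by log-parameterisation; trust-region reflective steps with
  xtol = ftol = gtol = 1e-14.
- Initial guesses: Vmax₀ = max(v); Km₀ = the concentration whose rate is
  nearest Vmax₀/2; Ki is multi-started from {max(s), s_peak²/Km₀, 10·Km₀}
  (the rate peak at s_peak implies Ki ≈ s_peak²/Km), keeping the lowest-cost
  solution — a single start at max(s) can stall in a local minimum when
  inhibition is strong.
- Standard errors: delta-method transforms of the Jacobian-based covariance
  at the optimum; no bootstrap.
- Guards: Km above 100× the largest sampled concentration, or below 1% of
  the smallest, is flagged unidentifiable. Ki is capped at 1e9 µM; a fit on
  the cap, or a fitted inhibition that depresses the rate by less than 0.1%
  of Vmax everywhere in the sampled range (undetectable by any realistic
  assay), downgrades the result to MM with a logged warning.
- Model choice: Haldane only when its AIC beats MM by more than 2 and Ki is
  reported; ties and everything else go to MM (parsimony). Known limitation:
  under 5% multiplicative noise this margin admits spurious inhibition in
  roughly 9% of MM-generated datasets, because unweighted OLS is
  miscalibrated when the error variance scales with the rate; the
  identifiability warnings and the materiality guard catch most, not all, of
  these. Power on strongly inhibited data is effectively 100%.
- Non-convergence is flagged on the result, never raised.

## Synthetic data: what it emulates

Generators are seeded (`numpy` Generator per call; identical seed ⇒
byte-identical output) and produce every input the pipeline reads.

- **Vial assays**: progress curves from integrating dS/dt = −v(S)·X/V
  (RK45, rtol 1e-8), sampled at {0, 0.5, 1, 1.5, 2, 4} h — five points over
  2 h plus a final point at 4 h — with additive Gaussian concentration noise
  (default σ = 0.2 µM, colorimetric-assay scale) clipped at zero. The vial
  protein load defaults to the value giving at most 20% substrate depletion
  at the lowest concentration over the window, an experimentally realistic
  signal-to-noise compromise; tests of estimator exactness use a much
  smaller depletion (1e-4) where the slope reads the initial rate to ~5e-5
  relative.
- **Rate datasets**: direct (s, v) draws with 5% multiplicative noise, the
  triplicate-vial noise scale used for recovery and model-selection checks.
- **Soil incubations**: treatment triples obeying the inhibitor logic
  (acetylene stops AOA+AOB, octyne stops AOB only) and mass balance — NH4⁺
  consumed equals NO2⁻+NO3⁻ produced; NO2⁻ accumulates by the flux excess of
  NH3 oxidation over the NOB potential, which is evaluated at the same
  assumed NO2⁻ concentrations the forward model consumes, so noise-free
  incubations and predictions are mutually consistent. Accumulation noise:
  additive, σ = 0.01 µmol g⁻¹ per 24 h.
- **Default ground truth**: one AOA (Km ≈ 6–20 µM total NH3+NH4⁺, Vmax
  rising to ~10.3 µmol mg⁻¹ h⁻¹, sub-mM Ki), one AOB (Vmax 51.5→128.7,
  Km 73.7→938.6 µM) and one Nitrobacter-like NOB (Vmax 33.6→102.4,
  Km 416.5→1662 µM NO2⁻) across 10–42 °C, parameters linear in temperature
  between the endpoints. Community descriptors (10⁸ AOA amoA, 5·10⁶ AOB
  amoA, 2·10⁶ nxrA copies g⁻¹; 1–2 copies genome⁻¹; 15–150 fg protein
  cell⁻¹) are synthetic fixture values on field-realistic scales, chosen so
  the soil is NOB-limited and NO2⁻ accumulates under NH4⁺ amendment
  (decoupled nitrification). Soil: 0.72 g water g⁻¹, 0.05 µmol g⁻¹
  extractable NH4⁺, pH 5.8, 5 µmol g⁻¹ NH4Cl amendment.

Not emulated: growth, pH drift or O2 limitation during incubations;
Griess-assay calibration; octyne/acetylene partial specificity; sorption or
diffusion in soil; microsite heterogeneity. Passing tests therefore show the
estimators and arithmetic are correct under the stated statistical model,
not that real soils satisfy the model's assumptions (uniform dissolution of
pools, fully active populations, pure-culture kinetics transferring to
communities).

## Other design decisions

- Units are fixed internally (µM, µmol · mg protein⁻¹ · h⁻¹, °C; Kelvin only
  inside speciation); I/O columns carry unit suffixes; all tables are long
  CSV, UTF-8, "." decimal, written at 17 significant digits and parsed with
  round-trip float precision so write∘read is the identity.
- Soil-solution concentrations are always computed from pools and water
  content at full precision; rounded presentation values in source tables
  are never hard-coded.
- Kinetic parameters at unmeasured incubation temperatures (e.g. 40 °C
  between assays at 37 and 42 °C) are linearly interpolated between
  bracketing measurements and flagged; extrapolation outside the measured
  range is refused unless exact-match mode is off and the caller opts in.
- The pipeline validates the incubation table in the partitioning stage
  before the forward model consumes its temperature grid, so a missing or
  incomplete treatment file aborts naming that stage.
- Sensitivity to the six uncertain forward-model inputs (population, protein
  per cell, copies per genome, Vmax, Km, Ki) is exposed as the full 2⁶ = 64
  mean ± SD combination grid; the default pipeline evaluates means only.

## Problem sizes

The test suite and acceptance script use: 100 random parameter draws for
noiseless recovery, 200 seeded replicates for noisy recovery and selection
statistics, 10⁵-point grids for the Haldane optimum, 3 organisms × 5 assay
temperatures × 8 concentrations for end-to-end runs, and 4 incubation
temperatures × 3 treatments × 3 replicates for partitioning.
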