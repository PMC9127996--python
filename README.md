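# nitrotherm

Temperature-resolved whole-cell kinetics of nitrification, and a forward model
that translates pure-culture kinetics plus qPCR abundances into predicted
potential soil nitrification rates.

## The problem

Nitrification — the two-step microbial oxidation of NH3 to NO2⁻ (by
ammonia-oxidizing archaea and bacteria, AOA and AOB) and of NO2⁻ to NO3⁻ (by
nitrite-oxidizing bacteria, NOB) — controls soil nitrogen availability, N2O
emissions and nitrate leaching. Its temperature response is usually modelled
with static substrate affinities, yet the apparent maximum rate *V*max(app)
and half-saturation constant *K*m(app) of whole cells both shift with
temperature, and differently in each nitrifier guild. `nitrotherm` is a
pipeline for researchers measuring those shifts in vial assays and asking
whether pure-culture kinetics can explain guild-level nitrification observed
in soil incubations.

## What it computes

**Whole-cell rate laws.** Oxidation rates *v* (µmol substrate · mg
protein⁻¹ · h⁻¹) at substrate concentration *S* (µM) follow Michaelis–Menten

&nbsp;&nbsp;&nbsp;&nbsp;*v* = *V*max · *S* / (*K*m + *S*)

or, where substrate inhibits, the Haldane law

&nbsp;&nbsp;&nbsp;&nbsp;*v* = *V*max · *S* / (*K*m + *S* + *S*²/*K*i)

whose optimum sits at *S*opt = √(*K*m·*K*i) with
*v*opt = *V*max/(1 + 2√(*K*m/*K*i)). Catalytic efficiency is *V*max/*K*m (the
low-substrate slope of either law); specific affinity a°s is exposed on the
same protein-normalised scale and the affinity constant as *K*A = 1/*K*m.

**The pipeline stages** (each also a standalone function and CLI subcommand):

1. `rates` — ordinary least-squares slopes of vial NO2⁻ time-courses
   (accumulation for NH3 oxidizers, disappearance for NOB), normalised by
   vial volume and mg cell protein;
2. `fitting` — nonlinear least squares for (*V*max, *K*m) and
   (*V*max, *K*m, *K*i), with AIC-based choice between MM and Haldane;
3. `speciation` — temperature- and pH-dependent NH3/NH4⁺ partitioning,
   fraction(NH3) = 1/(1 + 10^(p*K*a(T) − pH)), for re-expressing parameters
   on a free-NH3 basis;
4. `soil` — qPCR copies ÷ copies genome⁻¹ × protein cell⁻¹ → mg protein
   g soil⁻¹; substrate pools dissolved in gravimetric water → µM; rate law ×
   biomass → µmol g soil⁻¹ h⁻¹ per organism and temperature;
5. `partitioning` — 1-octyne/acetylene treatment differences decompose 24-h
   incubations into AOA, AOB and NOB rates (octyne inactivates AOB ammonia
   monooxygenase only; acetylene inactivates AOA and AOB);
6. `stats` — regression of observed guild rates on model predictions
   (R², slope, p).

A seeded synthetic-data module generates every input the pipeline consumes —
progress curves by integrating d*S*/d*t* = −*v*(*S*)·X/V, and mass-balanced
soil incubation triples from a known community — so the whole chain is
testable against known ground truth.

## Worked example

```python
from nitrotherm import (KineticParams, derive_kinetics, mm_rate, fold_change,
                        SpeciationContext, nh3_fraction, km_total_to_nh3)

# an AOB at 37 °C, parameters on the total NH3+NH4+ basis
p = KineticParams("AOB", "NH3_total", 37.0, vmax=128.7, km=938.6)
mm_rate(p, 938.6)                      # 64.35  — half of Vmax at S = Km
derive_kinetics(p).catalytic_efficiency  # 0.1371 (µmol mg⁻¹ h⁻¹)/µM
fold_change(73.7, 938.6)               # 12.7-fold Km rise across 10→37 °C

ctx = SpeciationContext(temperature=25.0, pH=8.0)
nh3_fraction(ctx)                      # 0.0537 — free NH3 share of the pool
km_total_to_nh3(938.6, ctx)            # 50.37 µM on the free-NH3 basis
```

End to end on synthetic data, from a shell:

```bash
nitrotherm simulate --seed 1 --out demo
nitrotherm compare --config demo/config.yaml
```

which fits kinetics from the generated vial time-courses, predicts potential
soil rates from the generated qPCR table, partitions the generated
incubations, and writes `demo/results/comparison.csv`:

```text
organism   model  r_squared  p_value  slope
 AOA_syn Haldane      0.983    0.009  1.096
 AOA_syn      MM      0.902    0.050  0.244
 AOB_syn Haldane      1.000    0.002  1.028
 AOB_syn      MM      1.000    0.000  0.962
 NOB_syn      MM      0.994    0.003  1.022
```

The AOA in this community is substrate-inhibited: the Haldane model tracks
its observed soil activity with slope ≈ 1, while the MM model overpredicts
(slope 0.24 — observed is a quarter of predicted). Intermediate artifacts
(`rates.csv`, `fits.csv`, `selected_params.csv`, `predictions.csv`,
`guild_rates.csv`, a manifest with the config hash and seed) land in the same
directory.

## Documentation

`docs/methods.md` describes the models, assumptions, default parameters,
numerical choices, and what the synthetic generators do and do not emulate.
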