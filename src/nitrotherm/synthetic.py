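"""Seeded generators for every input the pipeline consumes.

The generators emulate the two experimental designs the analysis assumes:

* **Vial kinetics assays** — progress curves of NO2⁻ accumulation (ammonia
  oxidizers) or disappearance (NOB) obtained by integrating dS/dt = −v(S)·X/V
  under the organism's MM or Haldane law, sampled at ~30 min intervals over
  2 h plus a final point at ~4 h, with additive Gaussian concentration noise
  (Griess-assay scale) clipped at zero.

* **24-h soil incubations** — treatment triples (none / +octyne / +acetylene)
  built from a known community and kinetics ground truth, obeying the
  inhibitor logic (acetylene stops AOA+AOB, octyne stops AOB only) and mass
  balance (NH4+ consumed = NO2⁻ + NO3⁻ produced), with matching qPCR tables.

Every generator takes its randomness from a single ``numpy`` Generator built
from an explicit seed, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .fitting import KineticDataset
from .kinetics import KineticParams, haldane_rate, mm_rate
from .partitioning import INCUBATION_HOURS, IncubationResult
from .rates import DEFAULT_VIAL_VOLUME_ML, Timecourse
from .soil import CellModel, SoilSample, params_at_temperature, protein_per_g, soil_solution_conc

__all__ = [
    "OrganismTruth",
    "GroundTruth",
    "default_ground_truth",
    "gen_rate_dataset",
    "gen_timecourses",
    "gen_soil_experiment",
]

#: Vial sampling schedule, h: five points over 2 h plus a final point at ~4 h.
SAMPLE_TIMES_H = (0.0, 0.5, 1.0, 1.5, 2.0, 4.0)


@dataclass(frozen=True)
class OrganismTruth:
    """Ground truth for one organism: kinetics across a temperature grid plus
    its community descriptors (qPCR marker, copies, per-cell protein)."""

    organism: str
    guild: str
    params: tuple[KineticParams, ...]
    marker: str
    gene_copies_per_g: float
    gene_copies_per_genome: int
    protein_per_cell_fg: float

    def cell_model(self) -> CellModel:
        return CellModel(self.organism, self.marker, self.gene_copies_per_genome,
                         self.protein_per_cell_fg)

    def params_at(self, temperature: float) -> tuple[KineticParams, bool]:
        return params_at_temperature(self.params, temperature)


@dataclass(frozen=True)
class GroundTruth:
    """Complete generating model: organisms, soil context and noise levels.

    ``sigma_rate`` is the multiplicative SD on rate observations,
    ``sigma_conc`` the additive SD (µM) on vial NO2⁻ readings, and
    ``sigma_soil`` the additive SD (µmol g⁻¹ / 24 h) on soil accumulations.
    """

    organisms: tuple[OrganismTruth, ...]
    soil: SoilSample
    seed: int
    sigma_rate: float = 0.05
    sigma_conc: float = 0.2
    sigma_soil: float = 0.01

    def organism(self, name: str) -> OrganismTruth:
        for o in self.organisms:
            if o.organism == name:
                return o
        raise KeyError(name)

    def noiseless(self) -> "GroundTruth":
        return replace(self, sigma_rate=0.0, sigma_conc=0.0, sigma_soil=0.0)


#: Kinetics assay temperature grid, °C (culture growth optima span 30–42 °C).
KINETIC_TEMPERATURES = (10.0, 20.0, 30.0, 37.0, 42.0)


def _interp_grid(temps: Sequence[float], lo: float, hi: float) -> list[float]:
    t = np.asarray(temps)
    return list(lo + (hi - lo) * (t - t[0]) / (t[-1] - t[0]))


def default_ground_truth(seed: int = 0) -> GroundTruth:
    """A realistic community + kinetics ground truth.

    Kinetic trajectories are anchored to the measured whole-cell ranges for
    soil nitrifiers: an AOA with low Km (~6–20 µM total NH3+NH4+), Vmax rising
    to ~10.3 µmol mg⁻¹ h⁻¹ and sub-mM substrate inhibition; an AOB whose Vmax
    rises 51.5→128.7 and Km 73.7→938.6 µM; and a Nitrobacter-like NOB with
    Vmax 33.6→102.4 and Km 416.5→1662 µM NO2⁻.  Community descriptors
    (copies g⁻¹, copies genome⁻¹, fg protein cell⁻¹) are synthetic fixture
    values on field-realistic scales, not measured quantities.
    """
    temps = KINETIC_TEMPERATURES
    aoa = OrganismTruth(
        "AOA_syn", "AOA",
        tuple(
            KineticParams("AOA_syn", "NH3_total", t, vmax, km, ki, source="synthetic ground truth")
            for t, vmax, km, ki in zip(
                temps,
                _interp_grid(temps, 0.10, 10.3),
                _interp_grid(temps, 6.1, 20.3),
                _interp_grid(temps, 300.0, 2400.0),
            )
        ),
        marker="AOA_amoA", gene_copies_per_g=1.0e8, gene_copies_per_genome=1,
        protein_per_cell_fg=15.0,
    )
    aob = OrganismTruth(
        "AOB_syn", "AOB",
        tuple(
            KineticParams("AOB_syn", "NH3_total", t, vmax, km, source="synthetic ground truth")
            for t, vmax, km in zip(
                temps,
                _interp_grid(temps, 51.5, 128.7),
                _interp_grid(temps, 73.7, 938.6),
            )
        ),
        marker="AOB_amoA", gene_copies_per_g=5.0e6, gene_copies_per_genome=2,
        protein_per_cell_fg=150.0,
    )
    nob = OrganismTruth(
        "NOB_syn", "NOB",
        tuple(
            KineticParams("NOB_syn", "NO2", t, vmax, km, source="synthetic ground truth")
            for t, vmax, km in zip(
                temps,
                _interp_grid(temps, 33.6, 102.4),
                _interp_grid(temps, 416.5, 1662.0),
            )
        ),
        # low NOB abundance: the soil is NOB-limited, so NO2⁻ accumulates
        # when NH4+ is added (decoupled nitrification)
        marker="nxrA", gene_copies_per_g=2.0e6, gene_copies_per_genome=2,
        protein_per_cell_fg=120.0,
    )
    soil = SoilSample(
        name="synthetic_loam",
        gene_copies_per_g={o.marker: o.gene_copies_per_g for o in (aoa, aob, nob)},
        water_content=0.72,
        extractable_nh4=0.05,
        pH=5.8,
        amendment_nh4=5.0,
        # assumed soil-solution NO2⁻ in amended incubations, µM, per temperature
        accumulated_no2_uM={10.0: 2.0, 20.0: 700.0, 30.0: 1900.0, 40.0: 400.0},
    )
    return GroundTruth(organisms=(aoa, aob, nob), soil=soil, seed=seed)


def _truth_rate(p: KineticParams, s: float, use_haldane: bool) -> float:
    return haldane_rate(p, s) if use_haldane and p.ki is not None else mm_rate(p, s)


def gen_rate_dataset(truth: OrganismTruth, temperature: float, s_grid: Sequence[float],
                     replicates: int = 3, sigma_rate: float = 0.05,
                     seed: int = 0, use_haldane: bool = True) -> KineticDataset:
    """Direct rate-versus-substrate observations with multiplicative noise:
    v_obs = v(s)·(1 + σ·ε), clipped at zero."""
    rng = np.random.default_rng(seed)
    p, _ = truth.params_at(temperature)
    obs = []
    for _ in range(replicates):
        for s in s_grid:
            v = _truth_rate(p, float(s), use_haldane)
            v_obs = v * (1.0 + sigma_rate * rng.standard_normal()) if sigma_rate > 0 else v
            obs.append((float(s), max(v_obs, 0.0)))
    return KineticDataset(truth.organism, truth.guild, temperature, tuple(obs))


def _integrate_progress(p: KineticParams, s0: float, protein_mg: float, volume_ml: float,
                        times: Sequence[float], use_haldane: bool) -> np.ndarray:
    """Substrate concentration S(t), µM, under dS/dt = −v(S)·X/V."""
    x_over_v = protein_mg / (volume_ml / 1000.0)  # mg protein per L

    def rhs(_t, y):
        s = max(y[0], 0.0)
        return [-_truth_rate(p, s, use_haldane) * x_over_v]

    sol = solve_ivp(rhs, (times[0], times[-1]), [s0], t_eval=list(times),
                    method="RK45", rtol=1e-8, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"progress-curve integration failed: {sol.message}")
    return np.clip(sol.y[0], 0.0, None)


def gen_timecourses(gt: GroundTruth, organism: str, temperatures: Sequence[float],
                    s_grid: Sequence[float], replicates: int = 3,
                    protein_mg: Optional[float] = None, max_depletion: float = 0.2,
                    volume_ml: float = DEFAULT_VIAL_VOLUME_ML,
                    times: Sequence[float] = SAMPLE_TIMES_H,
                    use_haldane: bool = True) -> list[Timecourse]:
    """Vial progress-curve set over an s-grid × replicates × temperatures design.

    When ``protein_mg`` is not given, the vial protein load is set so that at
    the lowest starting concentration no more than ``max_depletion`` of the
    substrate is consumed over the sampling window — the regime in which the
    time-course slope reads the initial rate.  Larger loads (or a larger
    ``max_depletion``) reproduce the curvature bias of depleting vials.
    """
    rng = np.random.default_rng(gt.seed)
    truth = gt.organism(organism)
    out: list[Timecourse] = []
    for temp in temperatures:
        p, _ = truth.params_at(temp)
        if protein_mg is None:
            s_min = float(min(s_grid))
            v_min = _truth_rate(p, s_min, use_haldane)
            prot = max_depletion * (volume_ml / 1000.0) * s_min / (v_min * times[-1])
        else:
            prot = protein_mg
        for s0 in s_grid:
            s_t = _integrate_progress(p, float(s0), prot, volume_ml, times, use_haldane)
            for rep in range(1, replicates + 1):
                if truth.guild == "NOB":
                    conc = s_t.copy()  # NO2⁻ is the depleting substrate
                else:
                    conc = float(s0) - s_t  # NO2⁻ accumulates as product
                if gt.sigma_conc > 0:
                    conc = conc + gt.sigma_conc * rng.standard_normal(conc.shape)
                conc = np.clip(conc, 0.0, None)
                out.append(Timecourse(
                    organism=truth.organism, guild=truth.guild, temperature=float(temp),
                    substrate_initial=float(s0), replicate=rep, protein_mg=prot,
                    points=tuple(zip(times, conc.tolist())), volume_ml=volume_ml,
                ))
    return out


def guild_truth_rates(gt: GroundTruth, temperature: float,
                      amended: bool) -> dict[str, float]:
    """Ground-truth guild fluxes (µmol g soil⁻¹ h⁻¹) at one temperature.

    Ammonia oxidizers run at the assumed soil-solution NH4+ concentration
    (Haldane only when amended); the NOB potential runs at the assumed NO2⁻
    concentration.  The realized NO2⁻ oxidation flux is capped by NH3
    oxidation supply (no initial NO2⁻ pool).
    """
    sample = gt.soil if amended else replace(gt.soil, amendment_nh4=0.0)
    s_nh4 = soil_solution_conc(sample, "nh4_amended" if amended else "nh4_native")
    rates: dict[str, float] = {"AOA": 0.0, "AOB": 0.0, "NOB_potential": 0.0}
    for o in gt.organisms:
        p, _ = o.params_at(temperature)
        prot = protein_per_g(o.gene_copies_per_g / o.gene_copies_per_genome, o.cell_model())
        if o.guild in ("AOA", "AOB"):
            rates[o.guild] += _truth_rate(p, s_nh4, use_haldane=amended) * prot
        else:
            s_no2 = soil_solution_conc(sample, "no2_assumed", temperature)
            rates["NOB_potential"] += _truth_rate(p, s_no2, use_haldane=amended) * prot
    return rates


def gen_soil_experiment(gt: GroundTruth, temperatures: Sequence[float], amendment: bool,
                        replicates: int = 3) -> tuple[list[IncubationResult], SoilSample]:
    """24-h incubation treatment triples from the community ground truth.

    Acetylene stops all NH3 oxidation; octyne leaves only AOA.  NO2⁻+NO3⁻
    accumulation equals NH3 oxidized (mass balance); NO2⁻ accumulates when
    the NOB potential cannot keep up with NH3 oxidation.  The NOB potential is
    evaluated at the soil's assumed NO2⁻ concentrations (its
    ``accumulated_no2_uM`` map when amended), the same input the forward
    model consumes, so noise-free incubations and predictions are consistent.
    """
    rng = np.random.default_rng(gt.seed + 1)
    h = INCUBATION_HOURS
    sample = gt.soil if amendment else replace(gt.soil, amendment_nh4=0.0)
    results: list[IncubationResult] = []
    for temp in temperatures:
        truth = guild_truth_rates(gt, float(temp), amendment)
        nob_pot = truth["NOB_potential"]
        for treatment, a_rate in (("none", truth["AOA"] + truth["AOB"]),
                                  ("octyne", truth["AOA"]),
                                  ("acetylene", 0.0)):
            nox = a_rate * h
            no2 = max(0.0, a_rate - nob_pot) * h
            for rep in range(1, replicates + 1):
                e1, e2 = (gt.sigma_soil * rng.standard_normal(2)
                          if gt.sigma_soil > 0 else (0.0, 0.0))
                results.append(IncubationResult(
                    soil=sample.name, temperature=float(temp), treatment=treatment,
                    nh4_added=amendment, no2_accum=no2 + e1, nox_accum=nox + e2,
                    replicate=rep,
                ))
    return results, sample
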