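"""Forward model: pure-culture kinetics + qPCR abundances → potential soil rates.

The chain of assumptions, applied per organism as if that strain made up the
entire population of its guild:

1. qPCR marker copies g soil⁻¹ ÷ gene copies genome⁻¹ → cells g⁻¹ (all copies
   assumed to come from active cells);
2. cells g⁻¹ × protein cell⁻¹ (fg) → mg cell protein g soil⁻¹;
3. extractable or amended substrate pools are assumed fully dissolved in the
   gravimetric soil water, giving a soil-solution concentration in µM;
4. the whole-cell MM or Haldane rate at that concentration × protein g⁻¹
   gives a potential rate in µmol substrate g soil⁻¹ h⁻¹.

NO2⁻ concentrations for the NOB predictions are assumed: without NH4+
amendment, the value obtained if all native NH4+ were oxidized; with
amendment, the measured accumulated NO2⁻ at each temperature, or the assay
detection limit (2 µM) when none accumulated.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .kinetics import KineticParams, haldane_rate, mm_rate

__all__ = [
    "SoilSample",
    "CellModel",
    "SoilPrediction",
    "cells_per_g",
    "protein_per_g",
    "soil_solution_conc",
    "predict_soil_rate",
    "params_at_temperature",
    "allowed_models",
    "averaged_inputs",
    "enumerate_extremes",
]

log = logging.getLogger(__name__)

MARKERS = ("AOA_amoA", "AOB_amoA", "nxrA", "nxrB")

#: Colorimetric NO2⁻ detection limit in soil, µM.
DEFAULT_NO2_DETECTION_LIMIT_UM = 2.0

#: Assumed NO2⁻ must sit this many orders below Ki before Haldane is dropped.
HALDANE_NEGLIGIBLE_RATIO = 1e-2


@dataclass(frozen=True)
class SoilSample:
    """Descriptors of one soil used in incubations and the forward model.

    gene_copies_per_g maps marker → copies g soil⁻¹; water_content is
    gravimetric (g water / g soil, numerically mL g⁻¹); NH4+ pools in
    µmol g⁻¹; accumulated_no2_uM maps incubation temperature (°C) → measured
    NO2⁻ (µM) in amended incubations.
    """

    name: str
    gene_copies_per_g: Mapping[str, float]
    water_content: float
    extractable_nh4: float
    pH: float
    amendment_nh4: float = 0.0
    accumulated_no2_uM: Mapping[float, float] = field(default_factory=dict)
    detection_limit_no2: float = DEFAULT_NO2_DETECTION_LIMIT_UM

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.gene_copies_per_g.values()):
            raise ValueError("gene copies must be nonnegative")
        if not 0 < self.water_content < 2:
            raise ValueError(f"water_content {self.water_content} outside (0, 2) g/g")
        if self.extractable_nh4 < 0 or self.amendment_nh4 < 0:
            raise ValueError("substrate pools must be nonnegative")


@dataclass(frozen=True)
class CellModel:
    """Per-cell conversion factors for one organism.

    ``protein_per_cell`` is in fg cell⁻¹; construct via :meth:`from_volume`
    when only a cell volume (µm³) and a protein-density coefficient
    (pg µm⁻³) are known.
    """

    organism: str
    marker: str
    gene_copies_per_genome: int
    protein_per_cell: float

    def __post_init__(self) -> None:
        if self.gene_copies_per_genome < 1:
            raise ValueError("gene_copies_per_genome must be >= 1")
        if not self.protein_per_cell > 0:
            raise ValueError("protein_per_cell must be positive")

    @classmethod
    def from_volume(cls, organism: str, marker: str, gene_copies_per_genome: int,
                    cell_volume_um3: float, protein_density_pg_per_um3: float) -> "CellModel":
        """Protein per cell from a cell volume × protein density (pg → fg)."""
        fg = cell_volume_um3 * protein_density_pg_per_um3 * 1000.0
        return cls(organism, marker, gene_copies_per_genome, fg)


@dataclass(frozen=True)
class SoilPrediction:
    """One organism's predicted potential rate at one temperature."""

    organism: str
    temperature: float
    model: str  # "MM" or "Haldane"
    substrate_conc_assumed: float  # µM
    rate: float  # µmol substrate g soil⁻¹ h⁻¹
    basis: str = "NH3_total"
    interpolated: bool = False


def cells_per_g(sample: SoilSample, cm: CellModel) -> float:
    """Marker copies g⁻¹ ÷ copies genome⁻¹ → cells g⁻¹."""
    if cm.marker not in sample.gene_copies_per_g:
        raise KeyError(f"marker {cm.marker!r} absent from soil {sample.name!r}")
    return sample.gene_copies_per_g[cm.marker] / cm.gene_copies_per_genome


def protein_per_g(cells: float, cm: CellModel) -> float:
    """Cells g⁻¹ × protein cell⁻¹ (fg) → mg protein g soil⁻¹ (×1e-12)."""
    if cells < 0:
        raise ValueError("cells must be nonnegative")
    return cells * cm.protein_per_cell * 1e-12


def soil_solution_conc(sample: SoilSample, pool: str,
                       temperature: Optional[float] = None) -> float:
    """Assumed soil-solution concentration (µM) for a substrate pool.

    ``nh4_native``: extractable NH4+ fully dissolved in the gravimetric water.
    ``nh4_amended``: the amendment pool fully dissolved (the native pool is
    not added, matching the stated incubation assumption).
    ``no2_assumed``: without amendment, the concentration if all native NH4+
    were oxidized to NO2⁻; with amendment, the measured accumulated NO2⁻ at
    ``temperature`` or the detection limit when none accumulated.

    µmol g⁻¹ ÷ (mL water g⁻¹) = µmol mL⁻¹ = mM; ×1000 → µM.
    """
    if not sample.water_content > 0:
        raise ValueError("water_content must be positive")
    per_pool = 1000.0 / sample.water_content  # µM per (µmol g⁻¹)
    if pool == "nh4_native":
        return sample.extractable_nh4 * per_pool
    if pool == "nh4_amended":
        if sample.amendment_nh4 <= 0:
            raise ValueError(f"soil {sample.name!r} has no NH4+ amendment")
        return sample.amendment_nh4 * per_pool
    if pool == "no2_assumed":
        if sample.amendment_nh4 <= 0:
            # all native NH4+ oxidized to NO2⁻
            return sample.extractable_nh4 * per_pool
        acc = sample.accumulated_no2_uM.get(temperature) if temperature is not None else None
        if acc is not None and acc > 0:
            return float(acc)
        log.info("soil %s @ %s C: no accumulated NO2⁻; assuming detection limit %.3g µM",
                 sample.name, temperature, sample.detection_limit_no2)
        return sample.detection_limit_no2
    raise ValueError(f"unknown pool {pool!r}")


def params_at_temperature(series: Sequence[KineticParams], temperature: float,
                          mode: str = "interpolate") -> tuple[KineticParams, bool]:
    """Kinetic parameters at an incubation temperature.

    Culture parameters exist at discrete assay temperatures; ``interpolate``
    linearly interpolates vmax/km/ki between the bracketing measurements
    (flagged in the returned bool), ``exact`` requires a measured match.
    Temperatures outside the measured range raise unless the bracketing is
    exact at an endpoint.
    """
    if not series:
        raise ValueError("empty parameter series")
    ordered = sorted(series, key=lambda p: p.temperature)
    temps = [p.temperature for p in ordered]
    for p in ordered:
        if p.temperature == temperature:
            return p, False
    if mode == "exact":
        raise ValueError(f"no kinetic parameters measured at {temperature} °C (have {temps})")
    if mode != "interpolate":
        raise ValueError(f"unknown temperature mode {mode!r}")
    if not temps[0] < temperature < temps[-1]:
        raise ValueError(
            f"{temperature} °C outside measured range [{temps[0]}, {temps[-1]}]; "
            "extrapolation is not enabled"
        )
    hi_idx = next(i for i, t in enumerate(temps) if t > temperature)
    lo, hi = ordered[hi_idx - 1], ordered[hi_idx]
    w = (temperature - lo.temperature) / (hi.temperature - lo.temperature)

    def lerp(a: Optional[float], b: Optional[float]) -> Optional[float]:
        if a is None or b is None:
            return None
        return a + w * (b - a)

    out = KineticParams(lo.organism, lo.substrate, temperature,
                        lerp(lo.vmax, hi.vmax), lerp(lo.km, hi.km), lerp(lo.ki, hi.ki),
                        source=f"interpolated {lo.temperature}-{hi.temperature} °C")
    log.info("interpolated %s kinetics at %.1f °C between %.1f and %.1f °C",
             lo.organism, temperature, lo.temperature, hi.temperature)
    return out, True


def predict_soil_rate(params: KineticParams, protein: float, s: float, model: str,
                      basis: str = "NH3_total", interpolated: bool = False) -> SoilPrediction:
    """Potential rate = whole-cell rate at the assumed concentration × protein.

    ``protein`` in mg g soil⁻¹, ``s`` in µM; returns µmol g soil⁻¹ h⁻¹.
    """
    if protein < 0:
        raise ValueError("protein must be nonnegative")
    if model == "MM":
        v = mm_rate(params, s)
    elif model == "Haldane":
        v = haldane_rate(params, s)
    else:
        raise ValueError(f"unknown model {model!r}")
    return SoilPrediction(params.organism, params.temperature, model, s, v * protein,
                          basis=basis, interpolated=interpolated)


def allowed_models(guild: str, amended: bool, s: float, ki: Optional[float],
                   negligible_ratio: float = HALDANE_NEGLIGIBLE_RATIO) -> tuple[str, ...]:
    """Which rate laws the forward model applies in a given incubation cell.

    Without NH4+ amendment no substrate inhibition of NH3 oxidation is
    assumed, so ammonia oxidizers get MM only.  For NOB, Haldane is dropped
    whenever the assumed NO2⁻ is orders of magnitude below Ki
    (s/Ki < ``negligible_ratio``), where inhibition is numerically irrelevant.
    """
    if ki is None:
        return ("MM",)
    if guild in ("AOA", "AOB") and not amended:
        log.info("no amendment: Haldane suppressed for %s", guild)
        return ("MM",)
    if guild == "NOB" and s / ki < negligible_ratio:
        log.info("assumed NO2⁻ %.3g µM << Ki %.3g µM: Haldane suppressed for NOB", s, ki)
        return ("MM",)
    return ("MM", "Haldane")


def averaged_inputs(inputs: Mapping[str, tuple[float, float]]) -> dict[str, float]:
    """Point inputs for the forward model: the mean of each uncertain input.

    ``inputs`` maps input name → (mean, SD).  The model is evaluated at the
    means; :func:`enumerate_extremes` provides the full ±SD combination grid
    for sensitivity runs.
    """
    return {name: mean for name, (mean, _) in inputs.items()}


def enumerate_extremes(inputs: Mapping[str, tuple[float, float]]) -> list[dict[str, float]]:
    """All 2^n combinations of mean ± SD over the n uncertain inputs
    (e.g. six inputs → 64 combinations)."""
    names = list(inputs)
    combos = []
    for signs in itertools.product((-1.0, 1.0), repeat=len(names)):
        combos.append({n: inputs[n][0] + sg * inputs[n][1] for n, sg in zip(names, signs)})
    return combos
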