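"""Michaelis–Menten and Haldane rate laws for whole-cell nitrifier kinetics.

Whole-cell oxidation kinetics are described by apparent parameters: Vmax(app),
the maximum substrate oxidation rate normalised per mg cell protein (a relative
kcat), and Km(app), the substrate concentration at half-maximal rate.  Substrate
inhibition, common in nitrifiers at high NH4+ or NO2- concentrations, is
captured by the Haldane extension with an inhibition constant Ki — the
substrate concentration that halves the apparent maximum rate.

Units are fixed throughout the package: concentrations in µM, rates in
µmol substrate · mg protein⁻¹ · h⁻¹, temperatures in °C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "KineticParams",
    "DerivedKinetics",
    "mm_rate",
    "haldane_rate",
    "haldane_optimum",
    "derive_kinetics",
    "fold_change",
]

#: Substrate bases a parameter set may be expressed on.
SUBSTRATES = ("NH3_total", "NH3_free", "NO2")


@dataclass(frozen=True)
class KineticParams:
    """Apparent whole-cell kinetic parameters at one organism × temperature.

    Parameters
    ----------
    organism : str
        Strain or organism identifier.
    substrate : str
        One of ``NH3_total`` (total NH3+NH4+), ``NH3_free`` (free NH3) or
        ``NO2``.
    temperature : float
        Assay temperature, °C.
    vmax : float
        Vmax(app), µmol substrate · mg protein⁻¹ · h⁻¹.
    km : float
        Km(app), µM.
    ki : float, optional
        Haldane substrate-inhibition constant, µM.  ``None`` means pure
        Michaelis–Menten behaviour (no detectable inhibition).
    source : str
        Free-text provenance of the values.
    """

    organism: str
    substrate: str
    temperature: float
    vmax: float
    km: float
    ki: Optional[float] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATES:
            raise ValueError(f"unknown substrate {self.substrate!r}; expected one of {SUBSTRATES}")
        if not self.vmax > 0:
            raise ValueError(f"vmax must be positive, got {self.vmax}")
        if not self.km > 0:
            raise ValueError(f"km must be positive, got {self.km}")
        if self.ki is not None and not self.ki > 0:
            raise ValueError(f"ki must be positive when present, got {self.ki}")
        if not 0.0 <= self.temperature <= 60.0:
            raise ValueError(f"temperature {self.temperature} °C outside [0, 60]")

    @property
    def has_inhibition(self) -> bool:
        return self.ki is not None


@dataclass(frozen=True)
class DerivedKinetics:
    """Quantities derived from a :class:`KineticParams`.

    ``catalytic_efficiency`` is Vmax/Km — the low-substrate slope of the rate
    law.  ``specific_affinity`` (a°s) is implemented on the same
    protein-normalised scale, i.e. identical to catalytic efficiency, and the
    affinity constant K_A as 1/Km; these are the limiting-slope and
    inverse-half-saturation definitions of the Button substrate-affinity
    framework.  The Haldane optimum fields are present only when Ki is.
    """

    catalytic_efficiency: float
    specific_affinity: float
    affinity_constant: float
    haldane_s_opt: Optional[float] = None
    haldane_v_opt: Optional[float] = None


def _check_conc(s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentration must be nonnegative")
    return s


def mm_rate(params: KineticParams, s):
    """Michaelis–Menten rate v = Vmax·S/(Km+S) at concentration ``s`` (µM).

    Accepts a scalar or array; returns the same shape.  Raises ``ValueError``
    for negative concentrations.
    """
    sv = _check_conc(s)
    out = params.vmax * sv / (params.km + sv)
    return float(out) if np.isscalar(s) or out.ndim == 0 else out


def haldane_rate(params: KineticParams, s):
    """Haldane rate v = Vmax·S/(Km + S + S²/Ki) at concentration ``s`` (µM).

    Requires ``params.ki``; raises ``ValueError`` otherwise.  Bounded above by
    the MM rate at the same (Vmax, Km) for every concentration.
    """
    if params.ki is None:
        raise ValueError(f"haldane_rate requires ki; params for {params.organism!r} have none")
    sv = _check_conc(s)
    out = params.vmax * sv / (params.km + sv + sv * sv / params.ki)
    return float(out) if np.isscalar(s) or out.ndim == 0 else out


def haldane_optimum(params: KineticParams) -> tuple[float, float]:
    """Concentration and rate at the Haldane maximum.

    Setting dv/dS = 0 in the Haldane law gives S_opt = sqrt(Km·Ki) and
    v_opt = Vmax / (1 + 2·sqrt(Km/Ki)).  As Ki → ∞ these recover the MM
    limit (S_opt → ∞, v_opt → Vmax).
    """
    if params.ki is None:
        raise ValueError("haldane_optimum requires ki")
    s_opt = math.sqrt(params.km * params.ki)
    v_opt = params.vmax / (1.0 + 2.0 * math.sqrt(params.km / params.ki))
    return s_opt, v_opt


def derive_kinetics(params: KineticParams) -> DerivedKinetics:
    """Compute catalytic efficiency, specific affinity a°s, K_A and, when Ki
    is present, the Haldane optimum."""
    eff = params.vmax / params.km
    s_opt = v_opt = None
    if params.ki is not None:
        s_opt, v_opt = haldane_optimum(params)
    return DerivedKinetics(
        catalytic_efficiency=eff,
        specific_affinity=eff,
        affinity_constant=1.0 / params.km,
        haldane_s_opt=s_opt,
        haldane_v_opt=v_opt,
    )


def fold_change(low: float, high: float) -> float:
    """Ratio high/low, e.g. the fold increase of Km(app) across a
    temperature range.  ``low`` must be positive."""
    if not low > 0:
        raise ValueError(f"fold_change requires positive low value, got {low}")
    return high / low
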