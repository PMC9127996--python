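"""Temperature- and pH-dependent NH3/NH4+ acid–base speciation.

Ammonia oxidizers consume NH3, but culture media and soil extractions are
quantified as total NH3+NH4+.  The free-NH3 fraction follows from the
temperature-dependent ammonium dissociation constant via

    fraction(NH3) = 1 / (1 + 10^(pKa(T) − pH)),
    pKa(T) = A + B / T_K                       (Emerson-type relation)

with defaults A = 0.09018 and B = 2729.92 K, the standard coefficients for
dilute aqueous solutions.  Ionic-strength corrections are not applied.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SpeciationContext",
    "pka_nh4",
    "nh3_fraction",
    "km_total_to_nh3",
    "km_nh3_to_total",
]

PKA_COEFF_A = 0.09018
PKA_COEFF_B = 2729.92  # Kelvin


@dataclass(frozen=True)
class SpeciationContext:
    """Aqueous conditions for NH3/NH4+ partitioning.

    temperature in °C (0–60), pH unitless (3–11); optional overrides for the
    two pKa coefficients.
    """

    temperature: float
    pH: float
    coeff_a: float = PKA_COEFF_A
    coeff_b: float = PKA_COEFF_B

    def __post_init__(self) -> None:
        if not 0.0 <= self.temperature <= 60.0:
            raise ValueError(f"temperature {self.temperature} °C outside [0, 60]")
        if not 3.0 <= self.pH <= 11.0:
            raise ValueError(f"pH {self.pH} outside [3, 11]")


def pka_nh4(ctx: SpeciationContext) -> float:
    """pKa of NH4+ at the context temperature (decreases with T)."""
    return ctx.coeff_a + ctx.coeff_b / (ctx.temperature + 273.15)


def nh3_fraction(ctx: SpeciationContext) -> float:
    """Fraction of total NH3+NH4+ present as free NH3; in (0, 1) and strictly
    increasing in both temperature and pH."""
    return 1.0 / (1.0 + 10.0 ** (pka_nh4(ctx) - ctx.pH))


def km_total_to_nh3(km_total: float, ctx: SpeciationContext) -> float:
    """Re-express a half-saturation constant from the total NH3+NH4+ basis to
    the free-NH3 basis: km_NH3 = km_total · fraction(NH3)."""
    if not km_total > 0:
        raise ValueError("km_total must be positive")
    return km_total * nh3_fraction(ctx)


def km_nh3_to_total(km_nh3: float, ctx: SpeciationContext) -> float:
    """Inverse of :func:`km_total_to_nh3`; the round trip is exact."""
    if not km_nh3 > 0:
        raise ValueError("km_nh3 must be positive")
    return km_nh3 / nh3_fraction(ctx)
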