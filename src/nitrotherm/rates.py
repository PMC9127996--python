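"""Oxidation-rate estimation from vial NO2⁻ time-courses.

NH3 oxidation rate is measured as the slope of NO2⁻ accumulation in a vial;
NO2⁻ oxidation rate as the slope of its disappearance (sign-flipped).  The
volumetric slope (µM h⁻¹) is converted to a whole-cell rate by multiplying by
the vial volume and dividing by the mg of cell protein added, giving
µmol substrate · mg protein⁻¹ · h⁻¹.

Vials are sampled at ~30 min intervals over 2 h with a final point at ~4 h;
at low substrate the curve bends as substrate depletes, so the all-points
slope underestimates the initial rate — the ``first_2h`` window limits that
bias at the cost of fewer points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .fitting import KineticDataset

__all__ = ["Timecourse", "RateObservation", "estimate_rate", "assemble_dataset"]

log = logging.getLogger(__name__)

GUILDS = ("AOA", "AOB", "NOB")

#: Default incubation vial volume, mL ("5 ml portions" of growth media).
DEFAULT_VIAL_VOLUME_ML = 5.0


@dataclass(frozen=True)
class Timecourse:
    """One vial's NO2⁻ concentration series.

    ``points`` is an ordered sequence of (time h, NO2⁻ µM) pairs starting near
    t=0; at least three points are required.
    """

    organism: str
    guild: str
    temperature: float
    substrate_initial: float
    replicate: int
    protein_mg: float
    points: tuple[tuple[float, float], ...]
    volume_ml: float = DEFAULT_VIAL_VOLUME_ML

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise ValueError(f"guild must be one of {GUILDS}, got {self.guild!r}")
        pts = tuple((float(t), float(c)) for t, c in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 3:
            raise ValueError("a timecourse needs at least 3 points")
        times = [t for t, _ in pts]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(c < 0 for _, c in pts):
            raise ValueError("concentrations must be nonnegative")
        if not self.protein_mg > 0:
            raise ValueError("protein_mg must be positive")
        if not self.volume_ml > 0:
            raise ValueError("volume_ml must be positive")


@dataclass(frozen=True)
class RateObservation:
    """A protein-normalised oxidation rate at one starting concentration."""

    organism: str
    guild: str
    temperature: float
    substrate_initial: float
    rate: float  # µmol · mg protein⁻¹ · h⁻¹, nonnegative after sign convention
    r_squared: float
    n_points_used: int


def estimate_rate(tc: Timecourse, window: str = "all_points") -> RateObservation:
    """Ordinary least-squares rate estimate from a vial time-course.

    ``window`` is ``all_points`` or ``first_2h`` (points with t ≤ 2 h).  The
    slope is sign-flipped for NOB (substrate disappearance).  A slope whose
    sign contradicts the guild's convention — NO2⁻ decreasing in an ammonia
    oxidizer vial, or increasing in a NOB vial — is clamped to zero with a
    logged warning rather than propagated, since downstream MM/Haldane fits
    assume nonnegative rates.
    """
    if window not in ("all_points", "first_2h"):
        raise ValueError(f"unknown window {window!r}")
    pts = tc.points if window == "all_points" else tuple(p for p in tc.points if p[0] <= 2.0)
    if len(pts) < 3:
        raise ValueError(f"window {window!r} leaves fewer than 3 points")
    t = np.array([p[0] for p in pts])
    c = np.array([p[1] for p in pts])
    fit = stats.linregress(t, c)
    slope = float(fit.slope)  # µM h⁻¹
    r2 = float(fit.rvalue**2) if np.std(c) > 0 else 1.0
    signed = -slope if tc.guild == "NOB" else slope
    if signed < 0:
        log.warning(
            "estimate_rate %s rep %d @ %.1f C, S0=%.3g µM: slope sign inconsistent with guild "
            "%s (%.3g µM/h); rate clamped to 0",
            tc.organism, tc.replicate, tc.temperature, tc.substrate_initial, tc.guild, slope,
        )
        signed = 0.0
    rate = signed * (tc.volume_ml / 1000.0) / tc.protein_mg
    return RateObservation(tc.organism, tc.guild, tc.temperature, tc.substrate_initial,
                           rate, r2, len(pts))


def assemble_dataset(rates: Iterable[RateObservation], organism: str,
                     temperature: float) -> KineticDataset:
    """Group rate observations into a fit-ready dataset.

    All observations must belong to the given organism and temperature;
    replicates at the same concentration are kept as separate observations,
    never averaged.  At least four distinct concentrations are required.
    """
    obs: Sequence[RateObservation] = list(rates)
    if not obs:
        raise ValueError("no rate observations supplied")
    bad = [o for o in obs if o.organism != organism or o.temperature != temperature]
    if bad:
        raise ValueError(
            f"mixed groups: expected {organism!r} @ {temperature} °C, found "
            f"{sorted({(o.organism, o.temperature) for o in bad})}"
        )
    guilds = {o.guild for o in obs}
    if len(guilds) != 1:
        raise ValueError(f"mixed guilds {sorted(guilds)}")
    return KineticDataset(
        organism=organism,
        guild=guilds.pop(),
        temperature=temperature,
        observations=tuple((o.substrate_initial, o.rate) for o in obs),
    )
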