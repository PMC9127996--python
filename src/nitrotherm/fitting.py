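"""Nonlinear least-squares estimation of whole-cell kinetic parameters.

Rates observed across a range of substrate concentrations are fit to the
Michaelis–Menten law (Vmax, Km) or the Haldane substrate-inhibition law
(Vmax, Km, Ki) by unweighted least squares on the rates.  Parameters are
log-transformed internally so positivity holds by construction, which avoids
negative-Km excursions on noisy data.  Standard errors come from the
Jacobian-based covariance at the optimum; model choice between MM and Haldane
uses an AIC margin of 2 with MM as the parsimony tie-break.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .kinetics import KineticParams

__all__ = [
    "KineticDataset",
    "FitResult",
    "fit_mm",
    "fit_haldane",
    "select_model",
    "KI_CAP_UM",
]

log = logging.getLogger(__name__)

#: Upper bound on Ki during Haldane fits (µM).  A fit that lands on this cap
#: means no detectable inhibition, and the MM fit is reported instead.
KI_CAP_UM = 1e9


@dataclass(frozen=True)
class KineticDataset:
    """Rate-versus-substrate observations for one organism × temperature.

    ``observations`` is a sequence of (s µM, v µmol mg⁻¹ h⁻¹) pairs; replicate
    measurements at the same concentration appear as separate entries.
    """

    organism: str
    guild: str
    temperature: float
    observations: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        obs = tuple((float(s), float(v)) for s, v in self.observations)
        object.__setattr__(self, "observations", obs)
        if any(s < 0 or v < 0 for s, v in obs):
            raise ValueError("all substrate concentrations and rates must be nonnegative")
        if len({s for s, _ in obs}) < 4:
            raise ValueError("kinetic fitting needs at least 4 distinct substrate concentrations")

    @property
    def s(self) -> np.ndarray:
        return np.array([s for s, _ in self.observations])

    @property
    def v(self) -> np.ndarray:
        return np.array([v for _, v in self.observations])


@dataclass(frozen=True)
class FitResult:
    """Outcome of one MM or Haldane fit."""

    params: KineticParams
    standard_errors: dict[str, float]
    residual_sum_squares: float
    aic: float
    converged: bool
    model: str  # "MM" or "Haldane"
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _mm_model(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * s / (km + s)


def _haldane_model(s: np.ndarray, vmax: float, km: float, ki: float) -> np.ndarray:
    return vmax * s / (km + s + s * s / ki)


def _aic(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood AIC; floor rss to keep it finite on exact fits.
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k


def _covariance_se(res, names: Sequence[str], theta: np.ndarray) -> dict[str, float]:
    """Delta-method standard errors on the natural scale from the Jacobian of
    the log-parameterised residuals."""
    n, k = res.fun.size, theta.size
    dof = max(n - k, 1)
    s2 = float(res.fun @ res.fun) / dof
    try:
        jtj = res.jac.T @ res.jac
        cov_log = s2 * np.linalg.inv(jtj)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0, np.inf))
    except np.linalg.LinAlgError:
        se_log = np.full(k, np.inf)
    # d(param)/d(log param) = param
    return {name: float(math.exp(t) * se) for name, t, se in zip(names, theta, se_log)}


def _initial_mm_guesses(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    vmax0 = float(np.max(v))
    if vmax0 <= 0:
        vmax0 = 1e-6
    half = vmax0 / 2.0
    pos = s[s > 0]
    km0 = float(s[np.argmin(np.abs(v - half))])
    if km0 <= 0:
        km0 = float(np.min(pos)) if pos.size else 1.0
    return vmax0, km0


def _run(ds: KineticDataset, model_fun, names: list[str], theta0: np.ndarray,
         bounds: tuple, weights: Optional[np.ndarray]) -> tuple:
    s, v = ds.s, ds.v
    w = np.ones_like(v) if weights is None else weights

    def residuals(theta):
        return w * (v - model_fun(s, *np.exp(theta)))

    res = least_squares(residuals, theta0, bounds=bounds, method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000)
    est = np.exp(res.x)
    # RSS on the fitted loss scale (weighted when weights are supplied), so
    # AIC comparisons stay consistent with the objective that was minimised
    rss = float(res.fun @ res.fun)
    ses = _covariance_se(res, names, res.x)
    return est, ses, rss, bool(res.success), res


def _weight_vector(ds: KineticDataset, weighting: Optional[str]) -> Optional[np.ndarray]:
    if weighting is None:
        return None
    if weighting == "1/v":
        v = ds.v
        return 1.0 / np.where(v > 0, v, np.min(v[v > 0]) if np.any(v > 0) else 1.0)
    raise ValueError(f"unknown weighting {weighting!r}")


def fit_mm(ds: KineticDataset, weighting: Optional[str] = None) -> FitResult:
    """Fit the Michaelis–Menten law to a dataset.

    Initial guesses: Vmax₀ = max(v); Km₀ = the concentration whose observed
    rate is nearest Vmax₀/2.  Non-convergence is flagged on the result, not
    raised.  A Km estimate beyond 100× the largest sampled concentration is
    flagged as unidentifiable.
    """
    vmax0, km0 = _initial_mm_guesses(ds.s, ds.v)
    theta0 = np.log([vmax0, km0])
    bounds = (np.log([1e-12, 1e-9]), np.log([1e12, 1e12]))
    est, ses, rss, ok, _ = _run(ds, _mm_model, ["vmax", "km"], theta0, bounds,
                                _weight_vector(ds, weighting))
    vmax, km = map(float, est)
    warns = []
    smax = float(np.max(ds.s))
    spos = ds.s[ds.s > 0]
    if km > 100.0 * smax:
        warns.append("km_unidentifiable: estimate exceeds 100x the largest sampled concentration")
    if spos.size and km < 0.01 * float(np.min(spos)):
        warns.append("km_below_sampled_range: estimate below the lowest sampled concentration")
    if not ok:
        warns.append("non_convergence")
    for w in warns:
        log.warning("fit_mm %s @ %.1f C: %s", ds.organism, ds.temperature, w)
    substrate = "NO2" if ds.guild == "NOB" else "NH3_total"
    params = KineticParams(ds.organism, substrate, ds.temperature, vmax, km, source="fit_mm")
    return FitResult(params, ses, rss, _aic(rss, ds.v.size, 2), ok, "MM", tuple(warns))


def fit_haldane(ds: KineticDataset, weighting: Optional[str] = None) -> FitResult:
    """Fit the Haldane substrate-inhibition law.

    Initial guesses come from :func:`fit_mm` plus Ki₀ = max(s).  Ki is capped
    at 10⁹ µM; a fit on the cap means no detectable inhibition, and the MM
    fit is returned instead (flagged in ``warnings``).  A relative Ki standard
    error above 1 flags Ki as unidentifiable — typical of designs with no
    concentrations above the apparent optimum sqrt(Km·Ki).
    """
    if len({s for s, _ in ds.observations}) < 5:
        raise ValueError("Haldane fitting needs at least 5 distinct substrate concentrations")
    mm = fit_mm(ds, weighting=weighting)
    smax = float(np.max(ds.s))
    # multi-start on Ki: the optimum lies at sqrt(Km·Ki), so a rate peak at
    # s_peak suggests Ki ≈ s_peak²/Km; a single start at max(s) can stall in
    # a local minimum when inhibition is strong
    s_peak = float(ds.s[int(np.argmax(ds.v))])
    ki_starts = {smax}
    if s_peak > 0 and mm.params.km > 0:
        ki_starts.add(min(max(s_peak**2 / mm.params.km, 1e-6), KI_CAP_UM))
    ki_starts.add(min(10.0 * mm.params.km, KI_CAP_UM))
    bounds = (np.log([1e-12, 1e-9, 1e-9]), np.log([1e12, 1e12, KI_CAP_UM]))
    best = None
    for ki0 in sorted(ki_starts):
        theta0 = np.log([mm.params.vmax, mm.params.km, ki0])
        attempt = _run(ds, _haldane_model, ["vmax", "km", "ki"], theta0, bounds,
                       _weight_vector(ds, weighting))
        if best is None or attempt[2] < best[2]:
            best = attempt
    est, ses, rss, ok, _ = best
    vmax, km, ki = map(float, est)
    # inhibition must be material over the sampled range: if the fitted
    # Haldane curve deviates from its own MM envelope by <0.1% of Vmax at
    # every sampled concentration, no assay could distinguish them
    s_all = ds.s[ds.s > 0]
    depression = (vmax * s_all / (km + s_all)
                  - vmax * s_all / (km + s_all + s_all**2 / ki))
    immaterial = s_all.size > 0 and float(np.max(depression)) < 1e-3 * vmax
    if ki >= 0.99 * KI_CAP_UM or immaterial:
        log.warning("fit_haldane %s @ %.1f C: Ki at cap, no detectable inhibition; reporting MM",
                    ds.organism, ds.temperature)
        return FitResult(mm.params, mm.standard_errors, mm.residual_sum_squares, mm.aic,
                         mm.converged, "MM",
                         mm.warnings + ("no_detectable_inhibition: Ki at cap, reporting MM",))
    warns = []
    se_ki = ses.get("ki", math.inf)
    if not math.isfinite(se_ki) or se_ki / ki > 1.0:
        warns.append("ki_unidentifiable: SE(Ki)/Ki > 1; design lacks concentrations above the optimum")
    if not ok:
        warns.append("non_convergence")
    for w in warns:
        log.warning("fit_haldane %s @ %.1f C: %s", ds.organism, ds.temperature, w)
    substrate = "NO2" if ds.guild == "NOB" else "NH3_total"
    params = KineticParams(ds.organism, substrate, ds.temperature, vmax, km, ki, source="fit_haldane")
    return FitResult(params, ses, rss, _aic(rss, ds.v.size, 3), ok, "Haldane", tuple(warns))


def select_model(mm: FitResult, haldane: FitResult) -> str:
    """Choose between MM and Haldane fits of the same dataset.

    Haldane is selected only when its AIC improves on MM by more than 2 and
    its Ki estimate is below the cap; MM wins ties (parsimony).
    """
    if haldane.model != "Haldane":  # downgraded at the cap
        return "MM"
    if haldane.converged and mm.aic - haldane.aic > 2.0:
        return "Haldane"
    return "MM"
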