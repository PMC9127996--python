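"""Guild partitioning of 24-h soil incubations via alkyne inhibitors.

1-Octyne irreversibly inactivates the bacterial ammonia monooxygenase only,
while acetylene inactivates both archaeal and bacterial AMO.  Differences in
NO2⁻+NO3⁻ accumulation between treatments therefore decompose nitrification:

    total AOA+AOB  = none − acetylene
    AOA only       = octyne − acetylene
    AOB            = total − AOA
    NOB            = total − NO2⁻ accumulation rate

all converted from 24-h accumulations (µmol g⁻¹ / 24 h) to hourly rates.
Small negative differences arise from assay noise; guild rates are physically
nonnegative, so negatives are clamped to zero and every clamp is logged.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

__all__ = ["IncubationResult", "GuildRates", "partition", "partition_all"]

log = logging.getLogger(__name__)

TREATMENTS = ("none", "octyne", "acetylene")
INCUBATION_HOURS = 24.0


@dataclass(frozen=True)
class IncubationResult:
    """One bottle's 24-h accumulation measurements.

    ``no2_accum`` and ``nox_accum`` (NO2⁻ and NO2⁻+NO3⁻) are in
    µmol g soil⁻¹ per 24 h; small negatives from assay noise are tolerated
    here and handled during partitioning.
    """

    soil: str
    temperature: float
    treatment: str
    nh4_added: bool
    no2_accum: float
    nox_accum: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")


@dataclass(frozen=True)
class GuildRates:
    """Partitioned hourly guild rates for one soil × temperature × amendment."""

    soil: str
    temperature: float
    nh4_added: bool
    total_nitrification: float
    aoa_rate: float
    aob_rate: float
    nob_rate: float
    n_replicates: int = 1
    sd_total: Optional[float] = None
    sd_aoa: Optional[float] = None
    sd_aob: Optional[float] = None
    sd_nob: Optional[float] = None


def _clamp(value: float, label: str, context: str) -> float:
    if value < 0:
        log.warning("partition %s: %s = %.4g < 0 clamped to 0", context, label, value)
        return 0.0
    return value


def _partition_once(none: IncubationResult, octyne: IncubationResult,
                    acetylene: IncubationResult, context: str) -> tuple[float, float, float, float]:
    h = INCUBATION_HOURS
    total = (none.nox_accum - acetylene.nox_accum) / h
    aoa = (octyne.nox_accum - acetylene.nox_accum) / h
    no2_rate = (none.no2_accum - acetylene.no2_accum) / h
    nob = total - no2_rate
    aoa = _clamp(aoa, "aoa", context)
    total = _clamp(total, "total", context)
    if aoa > total:  # noise can push AOA-only above total
        log.warning("partition %s: aoa %.4g exceeds total %.4g; aob clamped to 0", context, aoa, total)
        aoa = total
    aob = total - aoa
    nob = _clamp(nob, "nob", context)
    return total, aoa, aob, nob


def partition(replicates: Iterable[IncubationResult],
              mode: str = "per_replicate") -> GuildRates:
    """Partition one soil × temperature × amendment cell into guild rates.

    All three treatments must be present.  ``per_replicate`` (default)
    differences matched replicate triples then averages (treatments were
    applied to parallel bottles); ``averaged`` averages each treatment first
    and differences once.  Negative differences clamp to zero with a log
    entry in either mode.
    """
    results = list(replicates)
    keys = {(r.soil, r.temperature, r.nh4_added) for r in results}
    if len(keys) != 1:
        raise ValueError(f"partition expects a single soil × temperature × amendment cell, got {sorted(keys)}")
    soil, temp, amended = keys.pop()
    context = f"{soil} @ {temp} °C (NH4+ added: {amended})"
    by_treatment: dict[str, list[IncubationResult]] = defaultdict(list)
    for r in results:
        by_treatment[r.treatment].append(r)
    missing = [t for t in TREATMENTS if t not in by_treatment]
    if missing:
        raise ValueError(f"missing treatment(s) {missing} for {context}")

    if mode == "averaged":
        means = {
            t: IncubationResult(soil, temp, t, amended,
                                float(np.mean([r.no2_accum for r in rs])),
                                float(np.mean([r.nox_accum for r in rs])))
            for t, rs in by_treatment.items()
        }
        total, aoa, aob, nob = _partition_once(means["none"], means["octyne"],
                                               means["acetylene"], context)
        n = max(len(rs) for rs in by_treatment.values())
        return GuildRates(soil, temp, amended, total, aoa, aob, nob, n_replicates=n)
    if mode != "per_replicate":
        raise ValueError(f"unknown mode {mode!r}")

    by_rep: dict[int, dict[str, IncubationResult]] = defaultdict(dict)
    for r in results:
        if r.treatment in by_rep[r.replicate]:
            raise ValueError(f"duplicate {r.treatment!r} bottle for replicate {r.replicate} in {context}")
        by_rep[r.replicate][r.treatment] = r
    complete = {rep: trt for rep, trt in by_rep.items() if len(trt) == 3}
    if not complete:
        raise ValueError(f"no replicate with all three treatments for {context}")
    rows = np.array([
        _partition_once(trt["none"], trt["octyne"], trt["acetylene"], f"{context} rep {rep}")
        for rep, trt in sorted(complete.items())
    ])
    mean = rows.mean(axis=0)
    sd = rows.std(axis=0, ddof=1) if rows.shape[0] > 1 else np.full(4, np.nan)
    return GuildRates(soil, temp, amended, *map(float, mean), n_replicates=rows.shape[0],
                      sd_total=float(sd[0]), sd_aoa=float(sd[1]),
                      sd_aob=float(sd[2]), sd_nob=float(sd[3]))


def partition_all(results: Iterable[IncubationResult],
                  mode: str = "per_replicate") -> list[GuildRates]:
    """Partition every soil × temperature × amendment cell found in a table."""
    cells: dict[tuple, list[IncubationResult]] = defaultdict(list)
    for r in results:
        cells[(r.soil, r.temperature, r.nh4_added)].append(r)
    return [partition(rs, mode=mode) for _, rs in sorted(cells.items())]
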