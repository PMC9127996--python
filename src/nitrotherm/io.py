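"""CSV/YAML readers and writers, pipeline configuration, and the pipeline runner.

All tables are long (tidy) CSV, UTF-8, header row, "." decimal.  Temperatures
are °C and concentrations µM throughout I/O, with unit suffixes in column
names.  Every reader reports malformed rows with their file line numbers;
every writer produces a table its reader round-trips.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import FitResult, fit_haldane, fit_mm, select_model
from .kinetics import KineticParams
from .partitioning import GuildRates, IncubationResult, partition_all
from .rates import RateObservation, Timecourse, assemble_dataset, estimate_rate
from .soil import (CellModel, SoilPrediction, SoilSample, allowed_models, cells_per_g,
                   params_at_temperature, predict_soil_rate, protein_per_g,
                   soil_solution_conc)
from .speciation import SpeciationContext, km_total_to_nh3, nh3_fraction
from .stats import ModelFitSummary, compare

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "read_kinetic_params", "write_kinetic_params",
    "read_timecourses", "write_timecourses",
    "write_rate_observations",
    "write_fit_results",
    "read_incubations", "write_incubations",
    "write_guild_rates",
    "write_predictions",
    "write_comparisons",
    "read_soil_sample", "write_soil_sample",
    "read_cell_models", "write_cell_models",
]


# ---------------------------------------------------------------------------
# validation helpers

class ParseError(ValueError):
    """A malformed input table cell, reported with its file line number."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, cols: Sequence[str], path, optional: Sequence[str] = ()) -> pd.DataFrame:
    """Coerce columns to float, reporting the first bad cell with its line
    number (header = line 1)."""
    df = df.copy()
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna() & (df[c].astype(str).str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ParseError(f"{path}: non-numeric value {df[c][bad.idxmax()]!r} "
                             f"in column {c!r} at line {line}")
        if c not in optional and coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ParseError(f"{path}: missing value in column {c!r} at line {line}")
        df[c] = coerced
    return df


# ---------------------------------------------------------------------------
# kinetic parameter tables

KINETIC_PARAM_COLUMNS = ["organism", "substrate", "temperature_C", "vmax", "km", "ki", "source"]


def read_kinetic_params(path) -> list[KineticParams]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, KINETIC_PARAM_COLUMNS, path)
    df = _numeric(df, ["temperature_C", "vmax", "km", "ki"], path, optional=["ki"])
    out = []
    for _, r in df.iterrows():
        ki = None if pd.isna(r["ki"]) else float(r["ki"])
        src = "" if pd.isna(r["source"]) else str(r["source"])
        out.append(KineticParams(str(r["organism"]), str(r["substrate"]),
                                 float(r["temperature_C"]), float(r["vmax"]),
                                 float(r["km"]), ki, src))
    return out


def write_kinetic_params(params: Sequence[KineticParams], path) -> None:
    pd.DataFrame([
        {"organism": p.organism, "substrate": p.substrate, "temperature_C": p.temperature,
         "vmax": p.vmax, "km": p.km, "ki": p.ki, "source": p.source}
        for p in params
    ], columns=KINETIC_PARAM_COLUMNS).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# vial timecourses (long format)

TIMECOURSE_COLUMNS = ["organism", "guild", "temperature_C", "substrate_uM", "replicate",
                      "protein_mg", "volume_ml", "time_h", "no2_uM"]


def read_timecourses(path) -> list[Timecourse]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TIMECOURSE_COLUMNS, path)
    df = _numeric(df, ["temperature_C", "substrate_uM", "replicate", "protein_mg",
                       "volume_ml", "time_h", "no2_uM"], path)
    keys = ["organism", "guild", "temperature_C", "substrate_uM", "replicate",
            "protein_mg", "volume_ml"]
    out = []
    for key, grp in df.groupby(keys, sort=True):
        organism, guild, temp, s0, rep, prot, vol = key
        grp = grp.sort_values("time_h")
        out.append(Timecourse(str(organism), str(guild), float(temp), float(s0),
                              int(rep), float(prot),
                              tuple(zip(grp["time_h"], grp["no2_uM"])), float(vol)))
    return out


def write_timecourses(tcs: Sequence[Timecourse], path) -> None:
    rows = []
    for tc in tcs:
        for t, c in tc.points:
            rows.append({"organism": tc.organism, "guild": tc.guild,
                         "temperature_C": tc.temperature, "substrate_uM": tc.substrate_initial,
                         "replicate": tc.replicate, "protein_mg": tc.protein_mg,
                         "volume_ml": tc.volume_ml, "time_h": t, "no2_uM": c})
    pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def write_rate_observations(obs: Sequence[RateObservation], path) -> None:
    pd.DataFrame([dataclasses.asdict(o) for o in obs]).to_csv(path, index=False, float_format="%.17g")


def write_fit_results(fits: Sequence[FitResult], path) -> None:
    rows = []
    for f in fits:
        p = f.params
        rows.append({
            "organism": p.organism, "substrate": p.substrate, "temperature_C": p.temperature,
            "model": f.model, "vmax": p.vmax, "vmax_se": f.standard_errors.get("vmax"),
            "km": p.km, "km_se": f.standard_errors.get("km"),
            "ki": p.ki, "ki_se": f.standard_errors.get("ki") if p.ki is not None else None,
            "rss": f.residual_sum_squares, "aic": f.aic, "converged": f.converged,
            "warnings": "; ".join(f.warnings),
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# soil incubations and guild rates

INCUBATION_COLUMNS = ["soil", "temperature_C", "treatment", "nh4_added", "replicate",
                      "no2_umol_per_g_24h", "nox_umol_per_g_24h"]


def read_incubations(path) -> list[IncubationResult]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, INCUBATION_COLUMNS, path)
    df = _numeric(df, ["temperature_C", "replicate", "no2_umol_per_g_24h",
                       "nox_umol_per_g_24h"], path)
    return [IncubationResult(str(r["soil"]), float(r["temperature_C"]), str(r["treatment"]),
                             bool(r["nh4_added"]), float(r["no2_umol_per_g_24h"]),
                             float(r["nox_umol_per_g_24h"]), int(r["replicate"]))
            for _, r in df.iterrows()]


def write_incubations(results: Sequence[IncubationResult], path) -> None:
    pd.DataFrame([
        {"soil": r.soil, "temperature_C": r.temperature, "treatment": r.treatment,
         "nh4_added": r.nh4_added, "replicate": r.replicate,
         "no2_umol_per_g_24h": r.no2_accum, "nox_umol_per_g_24h": r.nox_accum}
        for r in results
    ], columns=INCUBATION_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def write_guild_rates(rates: Sequence[GuildRates], path) -> None:
    pd.DataFrame([dataclasses.asdict(g) for g in rates]).to_csv(path, index=False, float_format="%.17g")


def write_predictions(preds: Sequence[tuple[str, SoilPrediction]], path) -> None:
    """Rows of (soil name, prediction)."""
    pd.DataFrame([
        {"soil": soil, "organism": p.organism, "model": p.model, "temperature_C": p.temperature,
         "substrate_uM": p.substrate_conc_assumed, "rate_umol_per_g_per_h": p.rate,
         "basis": p.basis, "interpolated_flag": p.interpolated}
        for soil, p in preds
    ]).to_csv(path, index=False, float_format="%.17g")


def write_comparisons(summaries: Sequence[ModelFitSummary], path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# soil sample and cell models

def write_soil_sample(sample: SoilSample, path) -> None:
    doc = {
        "name": sample.name,
        "gene_copies_per_g": {k: float(v) for k, v in sample.gene_copies_per_g.items()},
        "water_content": sample.water_content,
        "extractable_nh4_umol_per_g": sample.extractable_nh4,
        "amendment_nh4_umol_per_g": sample.amendment_nh4,
        "pH": sample.pH,
        "accumulated_no2_uM": {float(k): float(v) for k, v in sample.accumulated_no2_uM.items()},
        "detection_limit_no2_uM": sample.detection_limit_no2,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


SOIL_KEYS = {"name", "gene_copies_per_g", "water_content", "extractable_nh4_umol_per_g",
             "amendment_nh4_umol_per_g", "pH", "accumulated_no2_uM", "detection_limit_no2_uM"}


def read_soil_sample(path) -> SoilSample:
    doc = yaml.safe_load(Path(path).read_text())
    unknown = set(doc) - SOIL_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown soil key(s) {sorted(unknown)}")
    missing = {"name", "gene_copies_per_g", "water_content", "extractable_nh4_umol_per_g", "pH"} - set(doc)
    if missing:
        raise ParseError(f"{path}: missing soil key(s) {sorted(missing)}")
    return SoilSample(
        name=doc["name"],
        gene_copies_per_g={str(k): float(v) for k, v in doc["gene_copies_per_g"].items()},
        water_content=float(doc["water_content"]),
        extractable_nh4=float(doc["extractable_nh4_umol_per_g"]),
        pH=float(doc["pH"]),
        amendment_nh4=float(doc.get("amendment_nh4_umol_per_g", 0.0)),
        accumulated_no2_uM={float(k): float(v) for k, v in doc.get("accumulated_no2_uM", {}).items()},
        detection_limit_no2=float(doc.get("detection_limit_no2_uM", 2.0)),
    )


CELL_MODEL_COLUMNS = ["organism", "guild", "marker", "gene_copies_per_genome", "protein_per_cell_fg"]


def read_cell_models(path) -> list[tuple[str, CellModel]]:
    """Rows of (guild, cell model)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, CELL_MODEL_COLUMNS, path)
    df = _numeric(df, ["gene_copies_per_genome", "protein_per_cell_fg"], path)
    return [(str(r["guild"]), CellModel(str(r["organism"]), str(r["marker"]),
                                        int(r["gene_copies_per_genome"]),
                                        float(r["protein_per_cell_fg"])))
            for _, r in df.iterrows()]


def write_cell_models(models: Sequence[tuple[str, CellModel]], path) -> None:
    pd.DataFrame([
        {"organism": cm.organism, "guild": guild, "marker": cm.marker,
         "gene_copies_per_genome": cm.gene_copies_per_genome,
         "protein_per_cell_fg": cm.protein_per_cell}
        for guild, cm in models
    ], columns=CELL_MODEL_COLUMNS).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`.

    File paths are resolved relative to the config file's directory when
    loaded via :meth:`from_yaml`.  Unknown keys are rejected.
    """

    timecourses_csv: str
    incubations_csv: str
    soil_yaml: str
    cell_models_csv: str
    out_dir: str
    seed: int = 0
    window: str = "all_points"           # rate-estimation window
    weighting: Optional[str] = None      # None or "1/v"
    basis: str = "NH3_total"             # or "NH3_free"
    temperature_mode: str = "interpolate"  # or "exact"
    partition_mode: str = "per_replicate"  # or "averaged"
    haldane_negligible_ratio: float = 1e-2
    speciation_coeff_a: float = 0.09018
    speciation_coeff_b: float = 2729.92

    def __post_init__(self) -> None:
        if self.window not in ("all_points", "first_2h"):
            raise ValueError(f"window must be all_points|first_2h, got {self.window!r}")
        if self.weighting not in (None, "1/v"):
            raise ValueError(f"weighting must be null or '1/v', got {self.weighting!r}")
        if self.basis not in ("NH3_total", "NH3_free"):
            raise ValueError(f"basis must be NH3_total|NH3_free, got {self.basis!r}")
        if self.temperature_mode not in ("interpolate", "exact"):
            raise ValueError(f"temperature_mode must be interpolate|exact, got {self.temperature_mode!r}")
        if self.partition_mode not in ("per_replicate", "averaged"):
            raise ValueError(f"partition_mode must be per_replicate|averaged, got {self.partition_mode!r}")

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text()) or {}
        cfg = cls.from_dict(doc)
        base = path.parent
        resolved = {f: str(base / getattr(cfg, f))
                    for f in ("timecourses_csv", "incubations_csv", "soil_yaml",
                              "cell_models_csv", "out_dir")
                    if not Path(getattr(cfg, f)).is_absolute()}
        return dataclasses.replace(cfg, **resolved)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# the pipeline

def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


@_stage("rate_estimation")
def _stage_rates(cfg: PipelineConfig, out: Path) -> list[RateObservation]:
    tcs = read_timecourses(cfg.timecourses_csv)
    obs = [estimate_rate(tc, window=cfg.window) for tc in tcs]
    write_rate_observations(obs, out / "rates.csv")
    return obs


@_stage("kinetic_fitting")
def _stage_fits(cfg: PipelineConfig, obs: list[RateObservation], out: Path) -> dict[str, dict]:
    by_group: dict[tuple[str, float], list[RateObservation]] = {}
    for o in obs:
        by_group.setdefault((o.organism, o.temperature), []).append(o)
    fits: list[FitResult] = []
    selected: dict[str, dict] = {}
    for (organism, temp), group in sorted(by_group.items()):
        ds = assemble_dataset(group, organism, temp)
        mm = fit_mm(ds, weighting=cfg.weighting)
        chosen = mm
        if len({s for s, _ in ds.observations}) >= 5:
            h = fit_haldane(ds, weighting=cfg.weighting)
            fits.extend([mm, h])
            if select_model(mm, h) == "Haldane":
                chosen = h
        else:
            fits.append(mm)
        info = selected.setdefault(organism, {"guild": ds.guild, "params": []})
        info["params"].append(chosen.params)
    write_fit_results(fits, out / "fits.csv")
    write_kinetic_params([p for info in selected.values() for p in info["params"]],
                         out / "selected_params.csv")
    return selected


@_stage("soil_model")
def _stage_soil(cfg: PipelineConfig, selected: dict[str, dict],
                out: Path) -> list[tuple[str, SoilPrediction]]:
    sample = read_soil_sample(cfg.soil_yaml)
    cell_models = {cm.organism: (guild, cm)
                   for guild, cm in read_cell_models(cfg.cell_models_csv)}
    incs = read_incubations(cfg.incubations_csv)
    temperatures = sorted({r.temperature for r in incs})
    amended = any(r.nh4_added for r in incs)
    preds: list[tuple[str, SoilPrediction]] = []
    for organism, info in sorted(selected.items()):
        if organism not in cell_models:
            raise KeyError(f"no cell model for organism {organism!r}")
        guild, cm = cell_models[organism]
        protein = protein_per_g(cells_per_g(sample, cm), cm)
        for temp in temperatures:
            p, interp = params_at_temperature(info["params"], temp, mode=cfg.temperature_mode)
            basis = cfg.basis
            if guild in ("AOA", "AOB"):
                s = soil_solution_conc(sample, "nh4_amended" if amended else "nh4_native")
                if cfg.basis == "NH3_free":
                    ctx = SpeciationContext(temp, sample.pH, cfg.speciation_coeff_a,
                                            cfg.speciation_coeff_b)
                    p = dataclasses.replace(
                        p, substrate="NH3_free", km=km_total_to_nh3(p.km, ctx),
                        ki=None if p.ki is None else km_total_to_nh3(p.ki, ctx))
                    s = s * nh3_fraction(ctx)
            else:
                s = soil_solution_conc(sample, "no2_assumed", temp)
                basis = "NO2"
            for model in allowed_models(guild, amended, s, p.ki,
                                        cfg.haldane_negligible_ratio):
                preds.append((sample.name,
                              predict_soil_rate(p, protein, s, model, basis=basis,
                                                interpolated=interp)))
    write_predictions(preds, out / "predictions.csv")
    return preds


@_stage("partitioning")
def _stage_partition(cfg: PipelineConfig, out: Path) -> list[GuildRates]:
    incs = read_incubations(cfg.incubations_csv)
    guilds = partition_all(incs, mode=cfg.partition_mode)
    write_guild_rates(guilds, out / "guild_rates.csv")
    return guilds


@_stage("comparison_stats")
def _stage_compare(cfg: PipelineConfig, selected: dict[str, dict],
                   preds: list[tuple[str, SoilPrediction]],
                   guilds: list[GuildRates], out: Path) -> list[ModelFitSummary]:
    cell_models = {cm.organism: guild for guild, cm in read_cell_models(cfg.cell_models_csv)}
    observed_by_guild: dict[str, dict[float, float]] = {"AOA": {}, "AOB": {}, "NOB": {}}
    for g in guilds:
        observed_by_guild["AOA"][g.temperature] = g.aoa_rate
        observed_by_guild["AOB"][g.temperature] = g.aob_rate
        observed_by_guild["NOB"][g.temperature] = g.nob_rate
    summaries = []
    by_org_model: dict[tuple[str, str, str], dict[float, float]] = {}
    for soil, p in preds:
        by_org_model.setdefault((soil, p.organism, p.model), {})[p.temperature] = p.rate
    for (soil, organism, model), series in sorted(by_org_model.items()):
        guild = cell_models.get(organism)
        obs = observed_by_guild.get(guild, {})
        temps = sorted(set(series) & set(obs))
        if len(temps) < 3:
            log.warning("comparison skipped for %s/%s: only %d matched temperatures",
                        organism, model, len(temps))
            continue
        summaries.append(compare([series[t] for t in temps], [obs[t] for t in temps],
                                 organism=organism, model=model, soil=soil))
    write_comparisons(summaries, out / "comparison.csv")
    return summaries


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full analysis and write every artifact to ``cfg.out_dir``.

    Stages run in order: rate estimation → kinetic fitting (with MM/Haldane
    model selection) → soil forward model (with optional free-NH3 basis via
    speciation) → guild partitioning → model-vs-observed regression.  A run
    manifest (config hash, seed, package version) makes reruns auditable;
    identical inputs give identical outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obs = _stage_rates(cfg, out)
    selected = _stage_fits(cfg, obs, out)
    # incubations are validated by the partitioning stage before the forward
    # model consumes their temperature grid
    guilds = _stage_partition(cfg, out)
    preds = _stage_soil(cfg, selected, out)
    _stage_compare(cfg, selected, preds, guilds, out)
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "nitrotherm_version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
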