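"""End-to-end orchestration: configuration, seeded runs, audit manifest.

Stages run in order — simulate (optional), salmon, design, fit,
summarize — reading and writing the delimited-text interchange files so
each stage can also be run standalone (or pointed at externally supplied
tables of the same schema, e.g. a re-analysis of the archived BC data).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from conflict_ecology import __version__
from conflict_ecology.predictors import build_design
from conflict_ecology.salmon import DEFAULT_SPECIES_MASS, process_streams
from conflict_ecology.model import (
    enumerate_candidates,
    fit_candidates,
    model_average,
    salmon_effect_percent,
)
from conflict_ecology.summaries import kde_density, seasonal_table
from conflict_ecology.synthetic import (
    LandscapeConfig,
    TruthParams,
    build_design_truth,
    generate_landscape,
    simulate_attacks,
    simulate_kills,
    simulate_salmon_streams,
    write_tables,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Flat run configuration; every analysis constant surfaces here."""

    data_dir: str = "data"
    out_dir: str = "out"
    mode: str = "salmon_areas"
    year_range: tuple[int, int] = (1980, 2013)
    cutoff: tuple[int, int] = (7, 1)
    window: int = 3
    n_imputations: int = 10
    quadrature_nodes: int = 15
    seed: int = 0
    species_mass: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_MASS)
    )
    excluded_units: list[str] = field(default_factory=list)
    simulate: bool = True
    n_units: int = 55
    frac_salmon_units: float = 0.45
    effect_fold: float = 0.5
    kde_bandwidth: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.year_range = tuple(cfg.year_range)  # type: ignore[assignment]
        cfg.cutoff = tuple(cfg.cutoff)  # type: ignore[assignment]
        return cfg

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_range[0], self.year_range[1] + 1)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def simulate_stage(config: RunConfig, truth: TruthParams | None = None) -> dict:
    """Generate the synthetic study tables into ``config.data_dir``."""
    truth = truth or TruthParams()
    lc = LandscapeConfig(
        n_units=config.n_units,
        year_range=config.year_range,
        frac_salmon_units=config.frac_salmon_units,
        seed=config.seed,
    )
    landscape = generate_landscape(lc, truth)
    streams = simulate_salmon_streams(landscape, truth, config.seed + 1)
    design_truth = build_design_truth(landscape, streams, truth)
    kills = simulate_kills(landscape, design_truth, truth, config.seed + 2)
    attacks = simulate_attacks(config.seed + 3)
    write_tables(config.data_dir, landscape, streams, kills, attacks, truth)
    return {
        "n_units": len(landscape.units),
        "n_stream_series": int(
            streams.groupby(["stream_id", "species"]).ngroups
        ) if not streams.empty else 0,
        "n_kill_records": len(kills),
        "n_attack_records": len(attacks),
    }


def _read(data_dir: str | Path, name: str) -> pd.DataFrame:
    path = Path(data_dir) / f"{name}.csv"
    if not path.exists():
        raise PipelineError(f"stage input missing: {path}")
    return pd.read_csv(path)


def salmon_stage(config: RunConfig) -> dict:
    streams = _read(config.data_dir, "streams")
    table, excluded = process_streams(
        streams,
        n_imputations=config.n_imputations,
        seed=config.seed + 10,
        species_mass=config.species_mass,
        years=config.years,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(out / "biomass.csv", index=False)
    table.unit_stats.to_csv(out / "biomass_units.csv", index=False)
    excluded.to_csv(out / "exclusions.csv", index=False)
    return {
        "n_series": int(streams.groupby(["stream_id", "species"]).ngroups)
        if not streams.empty
        else 0,
        "n_excluded_series": len(excluded),
        "n_unit_years_biomass": len(table.data),
    }


def design_stage(config: RunConfig) -> dict:
    kills = _read(config.data_dir, "kills")
    units = _read(config.data_dir, "units")
    census = _read(config.data_dir, "census")
    climate = _read(config.data_dir, "climate")
    out = Path(config.out_dir)
    biomass = None
    if config.mode == "salmon_areas":
        biomass = pd.read_csv(out / "biomass.csv")
    design = build_design(
        kills,
        units,
        census,
        climate,
        biomass,
        mode=config.mode,
        years=config.years,
        cutoff=config.cutoff,
        window=config.window,
        excluded_units=tuple(config.excluded_units),
    )
    design.data.to_csv(out / "design.csv", index=False)
    meta = {
        "annual_terms": design.annual_terms,
        "spatial_terms": design.spatial_terms,
        "mode": design.mode,
        "audit": design.audit,
    }
    (out / "design_meta.json").write_text(json.dumps(meta, indent=2))
    return {"n_design_rows": len(design.data), **design.audit}


def fit_stage(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    data = pd.read_csv(out / "design.csv")
    meta = json.loads((out / "design_meta.json").read_text())
    from conflict_ecology.predictors import DesignMatrix

    design = DesignMatrix(
        data=data,
        annual_terms=meta["annual_terms"],
        spatial_terms=meta["spatial_terms"],
        mode=meta["mode"],
    )
    candidates = enumerate_candidates(design)
    fits = fit_candidates(
        design, candidates, n_nodes=config.quadrature_nodes, seed=config.seed + 20
    )
    averaged = model_average(fits)
    weights = {tuple(f.terms): w for f, w in zip(averaged.fits, averaged.weights)}
    fit_rows = []
    for f in fits:
        fit_rows.append(
            {
                "terms": "+".join(t for t in f.terms),
                "loglik": f.loglik,
                "aicc": f.aicc,
                "phi": f.phi,
                "sigma_alpha": f.sigma_alpha,
                "converged": f.converged,
                "weight": weights.get(f.terms, 0.0),
            }
        )
    pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)
    averaged.table.to_csv(out / "averaged.csv", index=False)

    info: dict = {"n_candidates": len(fits),
                  "n_converged": sum(f.converged for f in fits)}
    if "salmon_biomass" in averaged.table["term"].values:
        stats = pd.read_csv(out / "biomass_units.csv")
        sd_avg = float(stats["sd_log_biomass"].mean())
        row = averaged.table.set_index("term").loc["salmon_biomass"]
        pct, ci = salmon_effect_percent(
            float(row["estimate"]),
            sd_avg,
            fold=config.effect_fold,
            beta_ci=(float(row["ci95_lo"]), float(row["ci95_hi"])),
        )
        effect = {
            "beta_salmon": float(row["estimate"]),
            "sd_avg_log_biomass": sd_avg,
            "fold": config.effect_fold,
            "percent_change": pct,
            "percent_change_ci95": list(ci),
            "rvi_salmon": float(row["rvi"]),
        }
        (out / "effect.json").write_text(json.dumps(effect, indent=2))
        info["salmon_effect_percent"] = pct
    return info


def summarize_stage(config: RunConfig) -> dict:
    kills = _read(config.data_dir, "kills")
    units = _read(config.data_dir, "units")
    attacks_path = Path(config.data_dir) / "attacks.csv"
    attacks = pd.read_csv(attacks_path) if attacks_path.exists() else None
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = seasonal_table(kills, units, attacks, cutoff=config.cutoff)
    table.to_csv(out / "seasonal.csv", index=False)
    conflict = kills[kills["kill_type"] == "conflict"]
    info = {"n_strata": len(table)}
    if {"x_km", "y_km"}.issubset(conflict.columns) and len(conflict):
        surface = kde_density(
            conflict[["x_km", "y_km"]], bandwidth=config.kde_bandwidth
        )
        surface.to_ascii_grid(out / "density.asc")
        info["kde_integral"] = surface.integral()
        info["kde_n_points"] = int(len(conflict))
    return info


STAGES = {
    "simulate": simulate_stage,
    "salmon": salmon_stage,
    "design": design_stage,
    "fit": fit_stage,
    "summarize": summarize_stage,
}


def run_pipeline(config: RunConfig, truth: TruthParams | None = None) -> dict:
    """Run all stages in order and write a manifest; fail naming the stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger("conflict_ecology").addHandler(handler)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    try:
        stage_names = (
            ["simulate", "salmon", "design", "fit", "summarize"]
            if config.simulate
            else ["salmon", "design", "fit", "summarize"]
        )
        for name in stage_names:
            try:
                if name == "simulate":
                    manifest["stages"][name] = simulate_stage(config, truth)
                else:
                    manifest["stages"][name] = STAGES[name](config)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )
    finally:
        logging.getLogger("conflict_ecology").removeHandler(handler)
        handler.close()
    return manifest
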