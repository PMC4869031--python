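"""Synthetic landscapes, salmon streams, climate, census and kill records.

Generates data with the statistical structure the downstream analysis
assumes: ~55 grizzly population units with habitable areas spanning roughly
2,700-49,000 km^2, stream-level Ricker-logistic salmon dynamics with
lognormal process error and missing observations, and annual conflict-kill
counts drawn from an NB2 count model with population random intercepts and
a log-habitable-area exposure offset.

Every function is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SPECIES = ("pink", "sockeye", "chum", "coho", "chinook")

ANNUAL_TERMS = (
    "salmon_biomass",
    "recent_conflict",
    "recent_hunt",
    "annual_temp",
    "annual_precip",
)
SPATIAL_TERMS = (
    "bear_density",
    "human_density",
    "normal_temp",
    "normal_precip",
    "salmon_present",
)


class ConfigurationError(ValueError):
    """Raised when a generator configuration field is invalid."""


class SimulationError(RuntimeError):
    """Raised when the generative model produces a non-finite mean."""


@dataclass(frozen=True)
class LandscapeConfig:
    """Layout of the synthetic study region.

    Defaults mirror the British Columbia study scale: 55 population units,
    habitable areas between 2,698 and 49,268 km^2, and the 1980-2013
    modelling window.
    """

    n_units: int = 55
    year_range: tuple[int, int] = (1980, 2013)
    habitable_area_range: tuple[float, float] = (2698.0, 49268.0)
    frac_salmon_units: float = 0.45
    streams_per_unit: tuple[int, int] = (3, 8)
    n_subdivisions: int = 120
    seed: int = 0

    def validate(self) -> None:
        if self.n_units < 2:
            raise ConfigurationError("n_units must be >= 2")
        lo, hi = self.year_range
        if hi - lo + 1 < 8:
            raise ConfigurationError("year_range must span at least 8 years")
        alo, ahi = self.habitable_area_range
        if alo <= 0 or ahi < alo:
            raise ConfigurationError(
                "habitable_area_range must be positive and ordered"
            )
        if not 0.0 <= self.frac_salmon_units <= 1.0:
            raise ConfigurationError("frac_salmon_units must lie in [0, 1]")
        slo, shi = self.streams_per_unit
        if slo < 1 or shi < slo:
            raise ConfigurationError("streams_per_unit must be ordered and >= 1")
        if self.n_subdivisions < 1:
            raise ConfigurationError("n_subdivisions must be >= 1")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_range[0], self.year_range[1] + 1)


@dataclass(frozen=True)
class TruthParams:
    """Generating parameters of the synthetic study.

    ``beta_annual`` and ``beta_spatial`` are coefficients on 2-SD scaled
    predictors, so their magnitudes are comparable across terms.  ``phi``
    is the NB2 size parameter (variance mu + mu^2/phi); the fitted values
    reported for the real system are in the 0.6-0.8 range.  ``alpha`` is
    chosen so the provincial total of conflict kills is of the observed
    order (~half a late-season kill per unit-year).
    """

    alpha: float = -10.2
    beta_annual: dict[str, float] = field(
        default_factory=lambda: {
            "salmon_biomass": -0.3,
            "recent_conflict": 0.1,
            "recent_hunt": 0.0,
            "annual_temp": 0.0,
            "annual_precip": 0.0,
        }
    )
    beta_spatial: dict[str, float] = field(
        default_factory=lambda: {
            "bear_density": 0.3,
            "human_density": 0.4,
            "normal_temp": 0.0,
            "normal_precip": 0.0,
            "salmon_present": 0.0,
        }
    )
    sigma_alpha: float = 0.4
    phi: float = 0.7
    ricker_r: float = 0.8
    ricker_K: float = 5000.0
    ricker_sigma: float = 0.3
    missing_rate: float = 0.1
    late_fraction: float = 0.82
    hunt_rate_per_1000km2: float = 0.15

    def validate(self) -> None:
        if self.phi <= 0:
            raise ConfigurationError("phi must be > 0")
        if self.sigma_alpha < 0:
            raise ConfigurationError("sigma_alpha must be >= 0")
        if self.ricker_K <= 0:
            raise ConfigurationError("ricker_K must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.late_fraction <= 1.0:
            raise ConfigurationError("late_fraction must lie in [0, 1]")


@dataclass
class Landscape:
    """Population units, census subdivisions and climate grids."""

    units: pd.DataFrame
    census: pd.DataFrame
    climate: pd.DataFrame
    config: LandscapeConfig
    random_intercepts: pd.Series  # per-unit deviations alpha_j

    @property
    def years(self) -> np.ndarray:
        return self.config.years


def generate_landscape(config: LandscapeConfig, truth: TruthParams) -> Landscape:
    """Draw a synthetic landscape of population units and covariates.

    Units get a habitable area (uniform on the configured range), a bear
    population implying densities of roughly 5-40 bears per 1,000 km^2, a
    salmon-presence flag, a planar centroid for kill locations, and a small
    climate grid.  Census subdivisions are generated directly as
    overlap-fraction tables (the analysis consumes only fractions); each
    subdivision's fractions across units sum to <= 1.
    """
    config.validate()
    truth.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_units
    unit_ids = [f"GBPU{i:03d}" for i in range(1, n + 1)]

    alo, ahi = config.habitable_area_range
    areas = rng.uniform(alo, ahi, size=n)
    # pin the extremes to the configured bounds so the range is exercised
    areas[np.argmin(areas)] = alo
    areas[np.argmax(areas)] = ahi

    bear_density = np.exp(rng.normal(np.log(15.0), 0.5, size=n))  # per 1000 km2
    bear_population = np.maximum(1, np.round(bear_density * areas / 1000.0))

    n_salmon = int(round(config.frac_salmon_units * n))
    salmon_present = np.zeros(n, dtype=bool)
    if n_salmon > 0:
        salmon_present[rng.choice(n, size=n_salmon, replace=False)] = True

    # planar centroids (km) on a rough grid; used only for KDE summaries
    side = int(np.ceil(np.sqrt(n)))
    cx = (np.arange(n) % side) * 150.0 + rng.uniform(-30, 30, size=n)
    cy = (np.arange(n) // side) * 150.0 + rng.uniform(-30, 30, size=n)

    units = pd.DataFrame(
        {
            "unit_id": unit_ids,
            "habitable_area_km2": areas,
            "bear_population": bear_population.astype(int),
            "salmon_present": salmon_present.astype(int),
            "centroid_x_km": cx,
            "centroid_y_km": cy,
        }
    )

    # census subdivisions: lognormal populations, 1-2 overlapping units
    rows = []
    for k in range(config.n_subdivisions):
        pop = int(np.round(np.exp(rng.normal(np.log(2000.0), 1.3))))
        j = int(rng.integers(0, n))
        if rng.random() < 0.25 and n > 1:
            j2 = int(rng.integers(0, n - 1))
            j2 = j2 + 1 if j2 >= j else j2
            f1 = rng.uniform(0.2, 0.8)
            rows.append((f"CSD{k:04d}", pop, unit_ids[j], round(f1, 4)))
            rows.append((f"CSD{k:04d}", pop, unit_ids[j2], round(1.0 - f1, 4)))
        else:
            rows.append((f"CSD{k:04d}", pop, unit_ids[j], 1.0))
    census = pd.DataFrame(
        rows, columns=["subdivision_id", "population", "unit_id", "overlap_frac"]
    )

    # climate grid: a handful of points per unit with normals, plus annual
    # values = normal + unit-year anomaly + point noise
    years = config.years
    base_temp = rng.normal(12.0, 2.0, size=n)  # spring-summer mean, deg C
    base_precip = np.exp(rng.normal(np.log(400.0), 0.4, size=n))  # mm
    anomalies_t = rng.normal(0.0, 1.0, size=(n, years.size))
    anomalies_p = rng.normal(0.0, 0.15, size=(n, years.size))
    clim_rows: list[tuple] = []
    for j in range(n):
        n_pts = max(3, int(round(areas[j] / 5000.0)))
        pt_t = base_temp[j] + rng.normal(0.0, 0.8, size=n_pts)
        pt_p = base_precip[j] * np.exp(rng.normal(0.0, 0.1, size=n_pts))
        for p in range(n_pts):
            clim_rows.append(
                (unit_ids[j], f"P{p:03d}", "normal", round(pt_t[p], 3), round(pt_p[p], 2))
            )
        for yi, year in enumerate(years):
            yt = pt_t + anomalies_t[j, yi] + rng.normal(0, 0.2, size=n_pts)
            yp = pt_p * np.exp(anomalies_p[j, yi] + rng.normal(0, 0.03, size=n_pts))
            for p in range(n_pts):
                clim_rows.append(
                    (unit_ids[j], f"P{p:03d}", str(year), round(yt[p], 3), round(yp[p], 2))
                )
    climate = pd.DataFrame(
        clim_rows, columns=["unit_id", "point_id", "period", "temp_c", "precip_mm"]
    )

    intercepts = pd.Series(
        rng.normal(0.0, truth.sigma_alpha, size=n), index=unit_ids, name="alpha_j"
    )
    return Landscape(
        units=units,
        census=census,
        climate=climate,
        config=config,
        random_intercepts=intercepts,
    )


def _ricker_step(n_t: np.ndarray | float, r: float, K: float) -> np.ndarray | float:
    return n_t * np.exp(r * (1.0 - n_t / K))


def simulate_salmon_streams(
    landscape: Landscape, truth: TruthParams, seed: int
) -> pd.DataFrame:
    """Simulate per-stream per-species escapement series with missingness.

    Counts follow N_{t+1} = N_t * exp(r (1 - N_t/K) + eps),
    eps ~ Normal(0, ricker_sigma^2), with stream-level capacities drawn
    lognormally around ``truth.ricker_K``.  Missing observations are
    injected independently at ``truth.missing_rate``.

    Returns a long DataFrame: stream_id, species, unit_id, year, count
    (NaN where missing), true_count (the complete series, for recovery
    tests).
    """
    rng = np.random.default_rng(seed)
    years = landscape.years
    salmon_units = landscape.units.loc[
        landscape.units["salmon_present"] == 1, "unit_id"
    ].tolist()
    slo, shi = landscape.config.streams_per_unit
    rows = []
    stream_counter = 0
    for unit_id in salmon_units:
        n_streams = int(rng.integers(slo, shi + 1))
        for _ in range(n_streams):
            stream_counter += 1
            stream_id = f"S{stream_counter:04d}"
            n_species = 1 + int(rng.random() < 0.4)
            species = rng.choice(SPECIES, size=n_species, replace=False)
            for sp in species:
                K = truth.ricker_K * np.exp(rng.normal(0.0, 0.6))
                r = truth.ricker_r
                n0 = K * np.exp(rng.normal(0.0, 0.3))
                series = np.empty(years.size)
                series[0] = n0
                eps = rng.normal(0.0, truth.ricker_sigma, size=years.size - 1)
                for t in range(years.size - 1):
                    series[t + 1] = series[t] * np.exp(
                        r * (1.0 - series[t] / K) + eps[t]
                    )
                missing = rng.random(years.size) < truth.missing_rate
                for t, year in enumerate(years):
                    rows.append(
                        (
                            stream_id,
                            sp,
                            unit_id,
                            int(year),
                            np.nan if missing[t] else round(series[t], 2),
                            round(series[t], 2),
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["stream_id", "species", "unit_id", "year", "count", "true_count"],
    )


def build_design_truth(
    landscape: Landscape,
    streams: pd.DataFrame,
    truth: TruthParams,
) -> pd.DataFrame:
    """Assemble the true scaled annual covariates used by the generator.

    Salmon biomass is the 2-SD-scaled log geometric-mean biomass computed
    from the *complete* stream series; annual climate values are scaled
    within unit.  Units without salmon carry 0 for the salmon column (the
    term is only active in salmon areas).
    """
    from conflict_ecology.predictors import climate_annual_means, gelman_scale
    from conflict_ecology.salmon import annual_population_biomass, DEFAULT_SPECIES_MASS

    years = landscape.years
    grid = pd.MultiIndex.from_product(
        [landscape.units["unit_id"], years], names=["unit_id", "year"]
    )
    design = pd.DataFrame(index=grid).reset_index()

    annual_clim = climate_annual_means(landscape.climate)
    annual_clim = annual_clim.rename(
        columns={"temp_mean": "annual_temp", "log_precip_total": "annual_precip"}
    )
    design = design.merge(annual_clim, on=["unit_id", "year"], how="left")
    for col in ("annual_temp", "annual_precip"):
        design[col] = design.groupby("unit_id")[col].transform(gelman_scale)

    design["salmon_biomass"] = 0.0
    if not streams.empty:
        complete = streams[
            ["stream_id", "species", "unit_id", "year", "true_count"]
        ].rename(columns={"true_count": "count"})
        table = annual_population_biomass(
            [complete], DEFAULT_SPECIES_MASS, years=years
        )
        design = design.merge(
            table.data[["unit_id", "year", "biomass_scaled"]],
            on=["unit_id", "year"],
            how="left",
        )
        design["salmon_biomass"] = design.pop("biomass_scaled").fillna(0.0)
    return design


def _random_dates(
    rng: np.random.Generator, year: int, n: int, late_fraction: float
) -> list[str]:
    """ISO dates with each kill independently late (on/after July 1)."""
    july1 = pd.Timestamp(year=year, month=7, day=1).dayofyear
    end = pd.Timestamp(year=year, month=12, day=31).dayofyear
    late = rng.random(n) < late_fraction
    days = np.where(
        late,
        rng.integers(july1, end + 1, size=n),
        rng.integers(1, july1, size=n),
    )
    base = pd.Timestamp(year=year, month=1, day=1)
    return [(base + pd.Timedelta(days=int(d) - 1)).strftime("%Y-%m-%d") for d in days]


def simulate_kills(
    landscape: Landscape,
    design_truth: pd.DataFrame,
    truth: TruthParams,
    seed: int,
) -> pd.DataFrame:
    """Draw conflict and hunt kill records from the generative count model.

    Annual conflict totals per unit are NB2(mu_ij, phi) with
    log mu_ij = alpha + alpha_j + X_ij . beta_annual + Z_j . beta_spatial
    + log A_j.  Each kill's date falls on/after July 1 with probability
    ``truth.late_fraction``; independent thinning preserves the NB2 family
    for the late-season response.  Hunt kills are Poisson at an
    area-proportional rate.  Recent-kill covariates enter as rolling 3-year
    sums scaled by fixed plug-in constants (exact within-unit scaling is
    circular at generation time).
    """
    from conflict_ecology.predictors import spatial_design

    rng = np.random.default_rng(seed)
    years = landscape.years
    units = landscape.units.set_index("unit_id")
    unit_ids = units.index.to_list()
    z = spatial_design(landscape.units, landscape.census, landscape.climate)

    beta_s = np.array([truth.beta_spatial[t] for t in SPATIAL_TERMS])
    z_mat = z.set_index("unit_id").loc[unit_ids, list(SPATIAL_TERMS)].to_numpy()
    areas = units["habitable_area_km2"].to_numpy()
    spatial_lp = truth.alpha + z_mat @ beta_s + np.log(areas)
    spatial_lp = spatial_lp + landscape.random_intercepts.loc[unit_ids].to_numpy()

    # plug-in centering/scaling constants for rolling-kill covariates
    mu_base = np.exp(spatial_lp)
    conf_center = 3.0 * mu_base
    conf_scale = 2.0 * np.sqrt(np.maximum(3.0 * mu_base * (1.0 + mu_base / truth.phi), 0.25))
    hunt_mu = truth.hunt_rate_per_1000km2 * areas / 1000.0
    hunt_center = 3.0 * hunt_mu
    hunt_scale = 2.0 * np.sqrt(np.maximum(3.0 * hunt_mu, 0.25))

    dt = design_truth.set_index(["unit_id", "year"])
    records: list[tuple] = []
    for j, unit_id in enumerate(unit_ids):
        conf_hist: list[int] = []
        hunt_hist: list[int] = []
        cxy = (units.at[unit_id, "centroid_x_km"], units.at[unit_id, "centroid_y_km"])
        for year in years:
            row = dt.loc[(unit_id, int(year))]
            x = {
                "salmon_biomass": float(row["salmon_biomass"]),
                "annual_temp": float(row["annual_temp"]),
                "annual_precip": float(row["annual_precip"]),
                "recent_conflict": (sum(conf_hist[-3:]) - conf_center[j]) / conf_scale[j],
                "recent_hunt": (sum(hunt_hist[-3:]) - hunt_center[j]) / hunt_scale[j],
            }
            lp = spatial_lp[j] + sum(
                truth.beta_annual[t] * x[t] for t in ANNUAL_TERMS
            )
            if not np.isfinite(lp):
                raise SimulationError(
                    f"non-finite linear predictor at unit {unit_id}, year {year}"
                )
            mu = np.exp(lp)
            lam = rng.gamma(shape=truth.phi, scale=mu / truth.phi)
            n_conflict = int(rng.poisson(lam))
            n_hunt = int(rng.poisson(hunt_mu[j]))
            conf_hist.append(n_conflict)
            hunt_hist.append(n_hunt)

            for date in _random_dates(rng, int(year), n_conflict, truth.late_fraction):
                records.append(
                    (
                        date,
                        unit_id,
                        "conflict",
                        max(0.5, rng.gamma(2.0, 1.5)),
                        float(np.exp(rng.normal(np.log(17.0), 0.8))),
                        cxy[0] + rng.normal(0, 25.0),
                        cxy[1] + rng.normal(0, 25.0),
                    )
                )
            # hunting season: spring + fall, uniform over Apr-Nov
            for _ in range(n_hunt):
                day = int(rng.integers(91, 335))
                date = (
                    pd.Timestamp(year=int(year), month=1, day=1)
                    + pd.Timedelta(days=day - 1)
                ).strftime("%Y-%m-%d")
                records.append(
                    (
                        date,
                        unit_id,
                        "hunt",
                        max(0.5, rng.gamma(3.5, 1.8)),
                        float(np.exp(rng.normal(np.log(44.0), 0.8))),
                        cxy[0] + rng.normal(0, 40.0),
                        cxy[1] + rng.normal(0, 40.0),
                    )
                )
    kills = pd.DataFrame(
        records,
        columns=[
            "date",
            "unit_id",
            "kill_type",
            "age",
            "distance_to_town_km",
            "x_km",
            "y_km",
        ],
    )
    kills["age"] = kills["age"].round(1)
    kills["distance_to_town_km"] = kills["distance_to_town_km"].round(1)
    return kills.sort_values(["date", "unit_id"], kind="stable").reset_index(drop=True)


def simulate_attacks(
    seed: int,
    year_range: tuple[int, int] = (1960, 2014),
    severe_rate: float = 1.18,
    minor_rate: float = 1.0,
    late_fraction: float = 0.81,
) -> pd.DataFrame:
    """Simulate bear-attack records with era-specific severity fields.

    Pre-1998 records carry hospitalization duration in hours; from 1998
    onwards only a hospitalization-required flag (mirroring the change in
    provincial record-keeping).  Severe attacks arrive at ``severe_rate``
    per year; a background of minor attacks is included so severity
    filtering is exercised.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for year in range(year_range[0], year_range[1] + 1):
        n_severe = int(rng.poisson(severe_rate))
        n_minor = int(rng.poisson(minor_rate))
        for kind in ["severe"] * n_severe + ["minor"] * n_minor:
            date = _random_dates(rng, year, 1, late_fraction)[0]
            fatal = kind == "severe" and rng.random() < 0.2
            if year < 1998:
                if kind == "severe":
                    hours = "" if fatal else round(float(rng.uniform(25, 400)), 1)
                else:
                    hours = round(float(rng.uniform(0, 24)), 1)
                rows.append((date, int(fatal), hours, ""))
            else:
                hosp = int(kind == "severe" and not fatal)
                rows.append((date, int(fatal), "", hosp))
    return pd.DataFrame(
        rows, columns=["date", "fatality", "hospital_hours", "hospitalized"]
    )


def write_tables(
    outdir: str | Path,
    landscape: Landscape,
    streams: pd.DataFrame,
    kills: pd.DataFrame,
    attacks: pd.DataFrame,
    truth: TruthParams,
) -> dict[str, Path]:
    """Write the delimited-text tables the pipeline reads, plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("units", landscape.units),
        ("census", landscape.census),
        ("climate", landscape.climate),
        ("streams", streams.drop(columns=["true_count"], errors="ignore")),
        ("kills", kills),
        ("attacks", attacks),
    ]:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    truth_path = outdir / "truth.json"
    payload = dataclasses.asdict(truth)
    payload["random_intercepts"] = landscape.random_intercepts.round(6).to_dict()
    truth_path.write_text(json.dumps(payload, indent=2))
    paths["truth"] = truth_path
    return paths
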