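"""Model design assembly: responses, rolling-kill covariates, spatial
covariates, human-density attribution, and 2-SD predictor scaling."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = (7, 1)  # July 1st, inclusive — approximate onset of hyperphagia


class InputError(ValueError):
    """Raised for invalid input tables (negative counts, missing units)."""


def gelman_scale(x) -> pd.Series | np.ndarray:
    """Centre and scale by two (sample) standard deviations.

    Returns (x - mean(x)) / (2 sd(x)) so a 1-unit change corresponds to a
    2-SD shift and coefficients are comparable with those of binary
    predictors.  Scaled values have mean 0 and SD 0.5; the transform is
    idempotent up to that normalisation and invariant to affine maps of
    the input.  A constant input (zero SD) yields NaN with a log entry,
    so the predictor drops out of the design.
    """
    arr = np.asarray(x, dtype=float)
    mean = np.nanmean(arr)
    sd = np.nanstd(arr, ddof=1) if np.sum(~np.isnan(arr)) > 1 else 0.0
    if not np.isfinite(sd) or sd == 0.0:
        logger.warning("gelman_scale: constant or degenerate input; returning NaN")
        out = np.full_like(arr, np.nan)
    else:
        out = (arr - mean) / (2.0 * sd)
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    return out


def late_season_counts(
    kills: pd.DataFrame,
    years: np.ndarray,
    units: list[str],
    cutoff: tuple[int, int] | None = DEFAULT_CUTOFF,
    excluded_units: tuple[str, ...] | list[str] = (),
    kill_type: str = "conflict",
) -> tuple[pd.DataFrame, dict]:
    """Count kills per unit-year, optionally restricted to the late season.

    Only records of ``kill_type`` dated on/after the (month, day) cutoff
    (inclusive) in non-excluded units within ``years`` are counted; pass
    ``cutoff=None`` for whole-year counts (used for the rolling
    predictors).  Unparseable dates are rejected with a log entry.
    Returns a complete unit x year grid (zeros filled) and an audit dict
    conserving record counts.
    """
    years = np.asarray(years)
    df = kills.copy()
    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    bad = dates.isna()
    if bad.any():
        for i in df.index[bad]:
            logger.warning("rejected record with unparseable date at row %s", i)
    df = df[~bad]
    dates = dates[~bad]
    df["year"] = dates.dt.year
    n_total = len(df)

    mask = df["kill_type"] == kill_type
    mask &= df["year"].isin(years)
    mask &= ~df["unit_id"].isin(list(excluded_units))
    if cutoff is not None:
        month, day = cutoff
        late = (dates.dt.month > month) | (
            (dates.dt.month == month) & (dates.dt.day >= day)
        )
        mask &= late
    counted = df[mask]
    grid = pd.MultiIndex.from_product([units, years], names=["unit_id", "year"])
    counts = (
        counted.groupby(["unit_id", "year"])
        .size()
        .reindex(grid, fill_value=0)
        .rename("count")
        .reset_index()
    )
    audit = {
        "n_records": n_total,
        "n_unparseable": int(bad.sum()),
        "n_counted": int(len(counted)),
        "n_excluded": n_total - int(len(counted)),
    }
    return counts, audit


def rolling_kills(counts: pd.DataFrame, window: int = 3) -> pd.DataFrame:
    """Sum of kill counts over the ``window`` years preceding each year.

    The current year is excluded: the value at year i is the sum over
    years i-1 .. i-window.  The first ``window`` years of each unit are
    unavailable (NaN) and are dropped from modelling.  Requires a
    contiguous year index per unit (as produced by late_season_counts).
    """
    if window < 1:
        raise InputError("rolling window must be >= 1")
    out = counts.sort_values(["unit_id", "year"]).copy()

    def _roll(s: pd.Series) -> pd.Series:
        return s.shift(1).rolling(window, min_periods=window).sum()

    out["rolling"] = out.groupby("unit_id")["count"].transform(_roll)
    return out[["unit_id", "year", "rolling"]]


def attribute_human_density(
    census: pd.DataFrame, units: pd.DataFrame
) -> pd.DataFrame:
    """People per km^2 of habitable area in each population unit.

    Each census subdivision's population is attributed to units in
    proportion to the fraction of the subdivision overlapping each unit:
    density_j = sum_k H_k f_kj / A_j.  When every subdivision is fully
    covered (fractions sum to 1), total population is conserved:
    sum_j density_j A_j = sum_k H_k.
    """
    if (census["population"] < 0).any():
        raise InputError("negative census population count")
    frac = census["overlap_frac"]
    if ((frac < 0) | (frac > 1)).any():
        raise InputError("overlap fractions must lie in [0, 1]")
    attributed = (
        census.assign(people=census["population"] * frac)
        .groupby("unit_id")["people"]
        .sum()
    )
    out = units[["unit_id", "habitable_area_km2"]].copy()
    out["human_density"] = (
        out["unit_id"].map(attributed).fillna(0.0) / out["habitable_area_km2"]
    )
    return out[["unit_id", "human_density"]]


def log_with_floor(x: pd.Series) -> pd.Series:
    """log(x + eps) with eps = half the smallest positive value (for zeros)."""
    positive = x[x > 0]
    if positive.empty:
        raise InputError("cannot log-transform an all-zero column")
    eps = positive.min() / 2.0
    if (x == 0).any():
        logger.info("log transform: %d zero(s) floored at %g", int((x == 0).sum()), eps)
    return np.log(x + np.where(x == 0, eps, 0.0))


def _grid_means(points: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    out = points.groupby(by, sort=True).agg(
        temp_mean=("temp_c", "mean"), precip_total=("precip_mm", "sum")
    )
    out["log_precip_total"] = np.log(out.pop("precip_total"))
    return out.reset_index()


def climate_normal_means(climate: pd.DataFrame) -> pd.DataFrame:
    """Per-unit climate-normal covariates from the 4-km grid points.

    Mean spring-summer temperature across the unit's points, and the log
    of the summed spring-summer precipitation.
    """
    normals = climate[climate["period"].astype(str) == "normal"]
    return _grid_means(normals, ["unit_id"])


def climate_annual_means(climate: pd.DataFrame) -> pd.DataFrame:
    """Per unit-year climate covariates (same definitions as the normals)."""
    annual = climate[climate["period"].astype(str) != "normal"].copy()
    annual["year"] = annual["period"].astype(int)
    return _grid_means(annual, ["unit_id", "year"])


def climate_grid_means(climate: pd.DataFrame, units: list[str] | None = None):
    """Normals and annual climate covariates; errors on units with no points."""
    normals = climate_normal_means(climate)
    if units is not None:
        missing = set(units) - set(normals["unit_id"])
        if missing:
            raise InputError(f"no climate grid points for unit(s): {sorted(missing)}")
    return normals, climate_annual_means(climate)


def spatial_design(
    units: pd.DataFrame,
    census: pd.DataFrame,
    climate: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Scaled spatial covariates Z_j, one row per population unit.

    Log bear density (2012-style population estimate over habitable
    area), log human density (with a half-minimum floor for empty units),
    climate normals, and the salmon-presence indicator, each centred and
    divided by 2 SD across units so effect sizes are comparable.  A
    constant column (e.g. salmon presence when every unit has salmon) is
    set to zero with a log entry — it carries no contrast.
    """
    z = units[["unit_id"]].copy()
    z["bear_density"] = np.log(
        units["bear_population"] / units["habitable_area_km2"]
    ).to_numpy()
    hd = attribute_human_density(census, units)
    z = z.merge(hd, on="unit_id")
    z["human_density"] = log_with_floor(z["human_density"])
    if climate is not None:
        normals = climate_normal_means(climate).rename(
            columns={"temp_mean": "normal_temp", "log_precip_total": "normal_precip"}
        )
        z = z.merge(normals, on="unit_id", how="left")
    else:
        z["normal_temp"] = 0.0
        z["normal_precip"] = 0.0
    z["salmon_present"] = units["salmon_present"].astype(float).to_numpy()
    for col in ("bear_density", "human_density", "normal_temp", "normal_precip", "salmon_present"):
        scaled = gelman_scale(z[col])
        if scaled.isna().all():
            logger.warning("spatial predictor %s is constant; set to 0", col)
            scaled = pd.Series(np.zeros(len(z)), index=z.index)
        z[col] = scaled
    return z


@dataclass
class DesignMatrix:
    """One-row-per-population-year model design (interchange: design.csv)."""

    data: pd.DataFrame
    annual_terms: list[str]
    spatial_terms: list[str]
    mode: str
    audit: dict = field(default_factory=dict)

    @property
    def all_terms(self) -> list[str]:
        return self.annual_terms + self.spatial_terms


def build_design(
    kills: pd.DataFrame,
    units: pd.DataFrame,
    census: pd.DataFrame,
    climate: pd.DataFrame,
    biomass: pd.DataFrame | None,
    mode: str = "full_region",
    years: np.ndarray | None = None,
    cutoff: tuple[int, int] = DEFAULT_CUTOFF,
    window: int = 3,
    excluded_units: tuple[str, ...] | list[str] = (),
) -> DesignMatrix:
    """Assemble the model design for one candidate-set mode.

    The response is the late-season conflict-kill count; the rolling-kill
    covariates use whole-year counts of the respective kill type.  Annual
    covariates (salmon biomass already scaled upstream; rolling kills and
    annual climate scaled here within unit) and spatial covariates
    (scaled across units) are joined with the log habitable-area offset.
    ``salmon_areas`` mode restricts to salmon-bearing units, includes the
    salmon-biomass term and drops the salmon-presence indicator;
    ``full_region`` keeps all units and the indicator but no biomass
    term.  The first ``window`` years of each unit, and any row with a
    missing predictor, are dropped.
    """
    if mode not in ("full_region", "salmon_areas"):
        raise InputError(f"unknown mode: {mode}")
    if years is None:
        yr = pd.to_datetime(kills["date"], errors="coerce").dt.year
        years = np.arange(int(yr.min()), int(yr.max()) + 1)
    years = np.asarray(years)

    keep_units = units[~units["unit_id"].isin(list(excluded_units))]
    if mode == "salmon_areas":
        keep_units = keep_units[keep_units["salmon_present"] == 1]
        if keep_units.empty:
            raise InputError("salmon_areas mode: no salmon-bearing units in input")
    unit_ids = keep_units["unit_id"].tolist()

    y_tab, audit = late_season_counts(
        kills, years, unit_ids, cutoff=cutoff, excluded_units=excluded_units
    )
    design = y_tab.rename(columns={"count": "y"})

    conf_all, _ = late_season_counts(
        kills, years, unit_ids, cutoff=None, excluded_units=excluded_units,
        kill_type="conflict",
    )
    hunt_all, _ = late_season_counts(
        kills, years, unit_ids, cutoff=None, excluded_units=excluded_units,
        kill_type="hunt",
    )
    rc = rolling_kills(conf_all, window).rename(columns={"rolling": "recent_conflict"})
    rh = rolling_kills(hunt_all, window).rename(columns={"rolling": "recent_hunt"})
    design = design.merge(rc, on=["unit_id", "year"]).merge(rh, on=["unit_id", "year"])

    _, annual_clim = climate_grid_means(climate, units=unit_ids)
    annual_clim = annual_clim.rename(
        columns={"temp_mean": "annual_temp", "log_precip_total": "annual_precip"}
    )
    design = design.merge(annual_clim, on=["unit_id", "year"], how="left")

    annual_terms = ["recent_conflict", "recent_hunt", "annual_temp", "annual_precip"]
    if mode == "salmon_areas":
        if biomass is None:
            raise InputError("salmon_areas mode requires a biomass table")
        design = design.merge(
            biomass[["unit_id", "year", "biomass_scaled"]].rename(
                columns={"biomass_scaled": "salmon_biomass"}
            ),
            on=["unit_id", "year"],
            how="left",
        )
        annual_terms = ["salmon_biomass"] + annual_terms

    for col in ("recent_conflict", "recent_hunt", "annual_temp", "annual_precip"):
        design[col] = design.groupby("unit_id")[col].transform(gelman_scale)

    z = spatial_design(keep_units.reset_index(drop=True), census, climate)
    spatial_terms = ["bear_density", "human_density", "normal_temp", "normal_precip"]
    if mode == "full_region":
        spatial_terms.append("salmon_present")
    design = design.merge(z[["unit_id"] + spatial_terms], on="unit_id")

    offsets = np.log(
        keep_units.set_index("unit_id")["habitable_area_km2"]
    )
    design["offset_log_area"] = design["unit_id"].map(offsets)

    n_before = len(design)
    design = design.dropna(subset=annual_terms + spatial_terms).reset_index(drop=True)
    audit["n_rows_dropped_na"] = n_before - len(design)
    audit["n_rows_design"] = len(design)
    cols = ["unit_id", "year", "y", "offset_log_area"] + annual_terms + spatial_terms
    return DesignMatrix(
        data=design[cols],
        annual_terms=annual_terms,
        spatial_terms=spatial_terms,
        mode=mode,
        audit=audit,
    )
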