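"""Descriptive summaries: monthly conflict tallies, late-season fractions,
severe-attack filtering, and kill-density hotspot surfaces."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = (7, 1)


@dataclass
class SeasonalSummary:
    """Monthly tally of records with the late-season (hyperphagia) share."""

    monthly: np.ndarray  # 12 counts, January first
    n_total: int
    n_late: int
    stratum: str = "all"

    @property
    def late_fraction(self) -> float:
        if self.n_total == 0:
            return np.nan
        return self.n_late / self.n_total

    @property
    def late_percent(self) -> int:
        """Late-season share rounded to the nearest whole percent."""
        return int(round(100.0 * self.late_fraction))


def seasonal_summary(
    records: pd.DataFrame,
    cutoff: tuple[int, int] = DEFAULT_CUTOFF,
    stratum: str = "all",
) -> SeasonalSummary:
    """Bin records by calendar month and compute the late-season fraction.

    The cutoff comparison is inclusive on month-day (a July 1 record is
    late).  An empty input yields n_total = 0 with an undefined (NaN)
    fraction.
    """
    dates = pd.to_datetime(records["date"], errors="coerce", format="ISO8601")
    ok = dates.notna()
    if (~ok).any():
        logger.warning("seasonal_summary: %d unparseable date(s) dropped", int((~ok).sum()))
    dates = dates[ok]
    monthly = np.bincount(dates.dt.month, minlength=13)[1:13]
    month, day = cutoff
    late = (dates.dt.month > month) | ((dates.dt.month == month) & (dates.dt.day >= day))
    summary = SeasonalSummary(
        monthly=monthly,
        n_total=int(len(dates)),
        n_late=int(late.sum()),
        stratum=stratum,
    )
    if summary.n_total == 0:
        logger.warning("seasonal_summary: no records in stratum %r", stratum)
    return summary


def filter_severe_attacks(attacks: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep only severe attacks, applying the era-appropriate rule.

    Pre-1998 records: fatality, or an injury requiring more than 24 hours
    of hospitalization (``hospital_hours`` > 24).  From 1998 onwards
    hospitalization duration is not recorded: fatality, or an injury of a
    severity requiring hospitalization (``hospitalized`` truthy).
    Records missing the era's severity field (and not fatal) are excluded
    with a log entry.  Deterministic: record order is irrelevant.
    """
    df = attacks.copy()
    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    year = dates.dt.year
    fatal = df["fatality"].fillna(0).astype(float) > 0

    hours = pd.to_numeric(df.get("hospital_hours"), errors="coerce")
    hosp = pd.to_numeric(df.get("hospitalized"), errors="coerce")

    pre = year < 1998
    severe_pre = pre & (fatal | (hours > 24))
    severe_post = ~pre & (fatal | (hosp > 0))
    missing_field = (~fatal) & ((pre & hours.isna()) | (~pre & hosp.isna()))
    n_missing = int(missing_field.sum())
    if n_missing:
        logger.warning("filter_severe_attacks: %d record(s) missing severity fields", n_missing)
    keep = (severe_pre | severe_post) & dates.notna()
    audit = {
        "n_records": int(len(df)),
        "n_severe": int(keep.sum()),
        "n_pre1998_rule": int((severe_pre & keep).sum()),
        "n_post1998_rule": int((severe_post & keep).sum()),
        "n_missing_severity": n_missing,
    }
    return df[keep].reset_index(drop=True), audit


@dataclass
class DensitySurface:
    """Gridded kill-density surface (kills per km^2)."""

    density: np.ndarray  # (ny, nx), row 0 = top (north)
    x_edges: np.ndarray
    y_edges: np.ndarray
    cell_size: float
    bandwidth: float

    def integral(self) -> float:
        return float(self.density.sum() * self.cell_size**2)

    def to_ascii_grid(self, path: str | Path) -> Path:
        """Write an ESRI ASCII-grid raster."""
        path = Path(path)
        ny, nx = self.density.shape
        header = (
            f"ncols {nx}\n"
            f"nrows {ny}\n"
            f"xllcorner {self.x_edges[0]:.6f}\n"
            f"yllcorner {self.y_edges[0]:.6f}\n"
            f"cellsize {self.cell_size:.6f}\n"
            "NODATA_value -9999\n"
        )
        body = "\n".join(
            " ".join(f"{v:.8g}" for v in row) for row in self.density
        )
        path.write_text(header + body + "\n")
        return path


def silverman_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """Rule-of-thumb bandwidth for a planar point set."""
    n = x.size
    sigma = np.sqrt(0.5 * (np.var(x) + np.var(y)))
    if sigma == 0 or n < 2:
        return 1.0
    return float(sigma * n ** (-1.0 / 6.0))


def kde_density(
    points: pd.DataFrame | np.ndarray,
    bandwidth: float | None = None,
    cell_size: float | None = None,
) -> DensitySurface:
    """Quartic-kernel (quadratic) density surface of kill locations.

    Each point contributes K(d) = 3/(pi h^2) (1 - d^2/h^2)^2 for d < h
    (Silverman's quartic kernel, the form used by GIS kernel-density
    tools), so the surface integrates to the number of points up to
    discretisation error.  Coordinates must be planar (projected, km);
    longitude/latitude-looking inputs are rejected with instructions to
    project first.
    """
    if isinstance(points, pd.DataFrame):
        geographic_names = {"lon", "lat", "longitude", "latitude"}
        if geographic_names & set(points.columns):
            raise ValueError(
                "input carries lon/lat columns; project to a planar "
                "coordinate system (km) before kernel density estimation"
            )
        if {"x_km", "y_km"}.issubset(points.columns):
            x = points["x_km"].to_numpy(dtype=float)
            y = points["y_km"].to_numpy(dtype=float)
        else:
            x = points.iloc[:, 0].to_numpy(dtype=float)
            y = points.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if x.size == 0:
        raise ValueError("kde_density needs at least one point")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(x, y)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    h = float(bandwidth)
    if cell_size is None:
        cell_size = h / 10.0
    c = float(cell_size)

    x_edges = np.arange(x.min() - h - c, x.max() + h + 2 * c, c)
    y_edges = np.arange(y.min() - h - c, y.max() + h + 2 * c, c)
    xc = x_edges[:-1] + c / 2.0
    yc = y_edges[:-1] + c / 2.0
    # evaluate at cell centres; top row = largest y so the raster reads north-up
    dens = np.zeros((yc.size, xc.size))
    norm = 3.0 / (np.pi * h**2)
    for px, py in zip(x, y):
        dx2 = (xc - px) ** 2
        dy2 = (yc - py) ** 2
        d2 = dy2[:, None] + dx2[None, :]
        inside = d2 < h**2
        dens[inside] += norm * (1.0 - d2[inside] / h**2) ** 2
    dens = dens[::-1, :]
    return DensitySurface(
        density=dens,
        x_edges=x_edges,
        y_edges=y_edges,
        cell_size=c,
        bandwidth=h,
    )


def seasonal_table(
    kills: pd.DataFrame,
    units: pd.DataFrame,
    attacks: pd.DataFrame | None = None,
    cutoff: tuple[int, int] = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Seasonal summaries for the standard strata, as one tidy table."""
    conflict = kills[kills["kill_type"] == "conflict"]
    salmon_units = set(units.loc[units["salmon_present"] == 1, "unit_id"])
    strata = {
        "all_kills": conflict,
        "salmon_areas": conflict[conflict["unit_id"].isin(salmon_units)],
        "non_salmon_areas": conflict[~conflict["unit_id"].isin(salmon_units)],
    }
    if attacks is not None:
        severe, _ = filter_severe_attacks(attacks)
        strata["severe_attacks"] = severe
    rows = []
    for name, df in strata.items():
        s = seasonal_summary(df, cutoff=cutoff, stratum=name)
        row = {
            "stratum": name,
            "n_total": s.n_total,
            "n_late": s.n_late,
            "late_percent": s.late_percent if s.n_total else np.nan,
        }
        row.update({f"m{m:02d}": int(s.monthly[m - 1]) for m in range(1, 13)})
        rows.append(row)
    return pd.DataFrame(rows)
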