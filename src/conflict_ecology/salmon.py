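"""Salmon escapement series: quality filtering, Ricker fits, imputation,
and aggregation to annual per-population biomass.

A stream-species series is modelled with the Ricker map with lognormal
process error, log(N_{t+1}/N_t) = r (1 - N_t/K) + eps.  Because the log
growth rate is linear in N_t, maximum-likelihood fitting reduces to
ordinary least squares of log(N_{t+1}/N_t) on N_t.  Missing counts are
multiply imputed by propagating the fitted map forward from the nearest
preceding observation with lognormal noise; annual population biomass is
the geometric mean, across a unit's streams, of combined-species stream
biomass, pooled across imputations on the log scale and then scaled by
two standard deviations within each unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

# mean spawner masses (kg); configurable, the real values are not published
DEFAULT_SPECIES_MASS: dict[str, float] = {
    "pink": 1.8,
    "sockeye": 2.7,
    "chum": 4.5,
    "coho": 3.2,
    "chinook": 8.0,
}

MAX_MISSING_TOTAL = 8
MAX_MISSING_RUN = 3


class FitError(RuntimeError):
    """Raised when a Ricker fit is requested on an inadequate series."""


@dataclass(frozen=True)
class RickerFit:
    """Ricker-logistic fit of one stream-species series.

    ``coef_cov`` (the unscaled OLS coefficient covariance (X'X)^-1) and
    ``ssr`` (residual sum of squares) carry the sampling distribution of
    the regression so imputation can propagate parameter uncertainty;
    fits built without them impute at the point estimates.
    """

    r: float
    K: float
    sigma: float
    loglik: float
    n_transitions: int
    valid: bool = True
    coef_cov: np.ndarray | None = None
    ssr: float | None = None

    def step(self, n_t):
        """Deterministic Ricker map N -> N exp(r (1 - N/K))."""
        return n_t * np.exp(self.r * (1.0 - n_t / self.K))


@dataclass
class BiomassTable:
    """Annual salmon biomass per population unit.

    ``data`` holds unit_id, year, biomass_kg (geometric mean across
    streams, pooled over imputations on the log scale) and biomass_scaled
    (log biomass centred and divided by 2 SD within unit).  ``unit_stats``
    holds the per-unit mean and SD of log biomass; the mean of the SD
    column across units is the "average salmon variability" used in the
    effect-size translation.
    """

    data: pd.DataFrame
    unit_stats: pd.DataFrame

    @property
    def sd_avg_log_biomass(self) -> float:
        return float(self.unit_stats["sd_log_biomass"].mean())


def _series_groups(streams: pd.DataFrame):
    return streams.groupby(["stream_id", "species"], sort=True)


def _missing_stats(counts: pd.Series) -> tuple[int, int]:
    """Total missing years and longest run of consecutive missing years."""
    miss = counts.isna().to_numpy()
    total = int(miss.sum())
    longest = run = 0
    for m in miss:
        run = run + 1 if m else 0
        longest = max(longest, run)
    return total, longest


def filter_series(
    streams: pd.DataFrame,
    max_missing_total: int = MAX_MISSING_TOTAL,
    max_missing_run: int = MAX_MISSING_RUN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the escapement-quality rules to stream-species series.

    A series is excluded iff it is missing more than ``max_missing_total``
    years in total, or has ``max_missing_run`` or more consecutive missing
    years.  Returns (retained rows, exclusions audit with the rule(s) that
    fired).  Idempotent and order-independent.
    """
    if streams.empty:
        empty_audit = pd.DataFrame(columns=["stream_id", "species", "reason"])
        return streams.copy(), empty_audit
    audit_rows = []
    keep_keys = []
    for (stream_id, species), grp in _series_groups(streams):
        grp = grp.sort_values("year")
        total, longest = _missing_stats(grp["count"])
        reasons = []
        if total > max_missing_total:
            reasons.append(f"total>{max_missing_total}")
        if longest >= max_missing_run:
            reasons.append(f"consecutive>={max_missing_run}")
        if reasons:
            audit_rows.append((stream_id, species, ";".join(reasons)))
        else:
            keep_keys.append((stream_id, species))
    keep = set(keep_keys)
    mask = [
        (s, sp) in keep for s, sp in zip(streams["stream_id"], streams["species"])
    ]
    retained = streams.loc[mask].reset_index(drop=True)
    excluded = pd.DataFrame(audit_rows, columns=["stream_id", "species", "reason"])
    return retained, excluded


def fit_ricker(series: pd.DataFrame) -> RickerFit:
    """Maximum-likelihood Ricker fit of one stream-species series.

    ``series`` needs columns year, count (NaN = missing).  The Gaussian
    likelihood of log(N_{t+1}/N_t) = r - (r/K) N_t + eps is maximised by
    OLS on the observed consecutive-year transitions; at least 3 are
    required.  A non-negative slope (no detectable density dependence)
    yields an invalid fit (K would be non-positive), for which callers
    fall back to mean imputation.
    """
    s = series.sort_values("year")
    years = s["year"].to_numpy()
    counts = s["count"].to_numpy(dtype=float)
    obs = ~np.isnan(counts) & (counts > 0)
    consec = obs[:-1] & obs[1:] & (np.diff(years) == 1)
    n_trans = int(consec.sum())
    if n_trans < 3:
        raise FitError(
            f"need >= 3 observed consecutive-year transitions, have {n_trans}"
        )
    n_t = counts[:-1][consec]
    n_t1 = counts[1:][consec]
    g = np.log(n_t1 / n_t)
    # OLS: g = a + b * N_t, with r = a, K = -a/b
    X = np.column_stack([np.ones_like(n_t), n_t])
    (a, b), *_ = np.linalg.lstsq(X, g, rcond=None)
    resid = g - (a + b * n_t)
    sigma = float(np.sqrt(np.mean(resid**2)))
    if sigma > 0:
        loglik = float(
            -0.5 * n_trans * np.log(2 * np.pi * sigma**2)
            - 0.5 * np.sum(resid**2) / sigma**2
        )
    else:
        loglik = np.inf
    valid = b < 0 and a > 0
    K = -a / b if valid else np.inf
    xtx_inv = np.linalg.inv(X.T @ X)
    return RickerFit(
        r=float(a),
        K=float(K),
        sigma=sigma,
        loglik=loglik,
        n_transitions=n_trans,
        valid=bool(valid),
        coef_cov=xtx_inv,
        ssr=float(np.sum(resid**2)),
    )


def _invert_ricker(fit: RickerFit, target: float) -> float:
    """Solve N exp(r (1 - N/K)) = target on the increasing branch N < K/r.

    The map is unimodal with maximum at N = K/r; targets above the maximum
    are clamped there.
    """
    upper = fit.K / max(fit.r, 1e-12)
    peak = fit.step(upper)
    if target >= peak:
        return float(upper)
    lo = min(target * 1e-6, 1e-9)
    return float(brentq(lambda n: fit.step(n) - target, lo, upper, xtol=1e-10))


def impute_series(
    series: pd.DataFrame,
    fit: RickerFit,
    n_imputations: int = 10,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Multiply impute missing counts by propagating the fitted Ricker map.

    Each missing year is filled from the nearest preceding filled value
    via one application of the map with multiplicative lognormal noise
    exp(sigma * z); a leading run of missing years is back-filled by
    numerically inverting the deterministic map from the first
    observation, with the same noise.  Observed values are never touched.
    Returns ``n_imputations`` completed copies; with sigma = 0 all copies
    coincide with the deterministic propagation.

    When the fit carries its OLS sampling distribution (``coef_cov`` and
    ``ssr``), each imputation first draws its own (r, K, sigma) from the
    normal-inverse-chi-squared posterior of the regression — proper
    multiple imputation in Rubin's sense, so across-imputation spread
    reflects parameter uncertainty as well as process noise.  Draws
    without density dependence (non-negative slope) fall back to the
    point estimates for that imputation.

    An invalid fit falls back to within-series mean imputation (logged).
    """
    s = series.sort_values("year").reset_index(drop=True)
    counts = s["count"].to_numpy(dtype=float)
    n_years = counts.size
    miss = np.isnan(counts)
    rng = np.random.default_rng(seed)
    M = n_imputations

    if not fit.valid:
        logger.warning(
            "invalid Ricker fit for stream %s; mean imputation",
            s["stream_id"].iat[0] if "stream_id" in s else "?",
        )
        mean_val = float(np.nanmean(counts))
        filled = np.where(miss, mean_val, counts)
        return [s.assign(count=filled) for _ in range(M)]

    # one parameter draw per imputation (point estimates if the fit does
    # not carry its sampling distribution, or the series was noiseless)
    dof = fit.n_transitions - 2
    draw_params = (
        fit.coef_cov is not None
        and fit.ssr is not None
        and fit.sigma > 0
        and dof >= 1
    )
    fits = []
    for _ in range(M):
        fit_m = fit
        if draw_params:
            sigma2_m = fit.ssr / rng.chisquare(dof)
            mean = np.array([fit.r, -fit.r / fit.K])
            a_m, b_m = rng.multivariate_normal(mean, sigma2_m * fit.coef_cov)
            if b_m < 0 and a_m > 0:
                fit_m = RickerFit(
                    r=float(a_m),
                    K=float(-a_m / b_m),
                    sigma=float(np.sqrt(sigma2_m)),
                    loglik=fit.loglik,
                    n_transitions=fit.n_transitions,
                )
        fits.append(fit_m)

    values = np.tile(counts, (M, 1))  # (M, n_years)
    first_obs = int(np.flatnonzero(~miss)[0]) if (~miss).any() else 0
    # back-fill a leading missing run from the first observation
    for t in range(first_obs - 1, -1, -1):
        # step-by-step deterministic preimage of the next (possibly imputed) value
        prev = np.empty(M)
        for m in range(M):
            det = _invert_ricker(fits[m], float(values[m, t + 1]))
            noise = (
                np.exp(fits[m].sigma * rng.standard_normal())
                if fits[m].sigma > 0
                else 1.0
            )
            prev[m] = det * noise
        values[:, t] = np.maximum(prev, 1e-9)
    for t in range(1, n_years):
        if not miss[t]:
            continue
        det = np.array([fits[m].step(values[m, t - 1]) for m in range(M)])
        noise = np.array(
            [
                np.exp(fits[m].sigma * rng.standard_normal())
                if fits[m].sigma > 0
                else 1.0
                for m in range(M)
            ]
        )
        values[:, t] = np.maximum(det * noise, 1e-9)
    return [s.assign(count=values[m]) for m in range(M)]


def gelman_scale_series(x: pd.Series) -> pd.Series:
    """(x - mean) / (2 * sample SD); see predictors.gelman_scale."""
    from conflict_ecology.predictors import gelman_scale

    return gelman_scale(x)


def annual_population_biomass(
    imputed_streams: list[pd.DataFrame],
    species_mass: dict[str, float] | None = None,
    years: np.ndarray | None = None,
) -> BiomassTable:
    """Aggregate completed stream series to annual unit-level biomass.

    Per stream-year: biomass = sum over species of count x mean mass.
    Per unit-year: geometric mean across the unit's streams of the
    combined-species stream biomass.  Log biomass is averaged across
    imputations (single pooled series per unit), then centred and divided
    by 2 SD within each unit.  Zero stream-year biomasses are replaced by
    half the smallest positive biomass observed in that stream (log(0) is
    undefined); the replacement count is recorded in the table's
    ``unit_stats.attrs['n_zero_replaced']``.
    """
    species_mass = dict(DEFAULT_SPECIES_MASS if species_mass is None else species_mass)
    log_unit_year: list[pd.Series] = []
    n_zero = 0
    for imp in imputed_streams:
        present = set(imp["species"].unique())
        missing_sp = present - set(species_mass)
        if missing_sp:
            raise KeyError(
                f"species absent from mass table: {sorted(missing_sp)}"
            )
        df = imp.copy()
        if years is not None:
            df = df[df["year"].isin(np.asarray(years))]
        df["biomass"] = df["count"] * df["species"].map(species_mass)
        stream_year = (
            df.groupby(["unit_id", "stream_id", "year"], sort=True)["biomass"]
            .sum()
            .reset_index()
        )
        zero = stream_year["biomass"] <= 0
        if zero.any():
            n_zero += int(zero.sum())
            floor = (
                stream_year[~zero]
                .groupby("stream_id")["biomass"]
                .min()
                .mul(0.5)
            )
            stream_year.loc[zero, "biomass"] = (
                stream_year.loc[zero, "stream_id"].map(floor).fillna(1e-6)
            )
        stream_year["log_biomass"] = np.log(stream_year["biomass"])
        # geometric mean across streams = exp(mean of logs)
        luy = stream_year.groupby(["unit_id", "year"], sort=True)["log_biomass"].mean()
        log_unit_year.append(luy)
    pooled = pd.concat(log_unit_year, axis=1).mean(axis=1).rename("log_biomass")
    data = pooled.reset_index()
    data["biomass_kg"] = np.exp(data["log_biomass"])
    from conflict_ecology.predictors import gelman_scale

    data["biomass_scaled"] = data.groupby("unit_id")["log_biomass"].transform(
        gelman_scale
    )
    unit_stats = (
        data.groupby("unit_id")["log_biomass"]
        .agg(mean_log_biomass="mean", sd_log_biomass=lambda v: v.std(ddof=1))
        .reset_index()
    )
    unit_stats.attrs["n_zero_replaced"] = n_zero
    return BiomassTable(
        data=data[["unit_id", "year", "biomass_kg", "biomass_scaled"]],
        unit_stats=unit_stats,
    )


def process_streams(
    streams: pd.DataFrame,
    n_imputations: int = 10,
    seed: int = 0,
    species_mass: dict[str, float] | None = None,
    years: np.ndarray | None = None,
) -> tuple[BiomassTable, pd.DataFrame]:
    """Filter, fit, impute and aggregate: the full salmon stage.

    Returns the biomass table and the exclusions audit.  Series whose
    Ricker fit fails (too few transitions or no density dependence) fall
    back to mean imputation rather than being dropped.
    """
    retained, excluded = filter_series(streams)
    if retained.empty:
        empty = BiomassTable(
            data=pd.DataFrame(columns=["unit_id", "year", "biomass_kg", "biomass_scaled"]),
            unit_stats=pd.DataFrame(columns=["unit_id", "mean_log_biomass", "sd_log_biomass"]),
        )
        return empty, excluded
    rng = np.random.default_rng(seed)
    completed: list[list[pd.DataFrame]] = [[] for _ in range(n_imputations)]
    for (stream_id, species), grp in _series_groups(retained):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            fit = fit_ricker(grp)
        except FitError:
            fit = RickerFit(0.0, np.inf, 0.0, -np.inf, 0, valid=False)
        imps = impute_series(grp, fit, n_imputations=n_imputations, seed=sub_seed)
        for m in range(n_imputations):
            completed[m].append(imps[m])
    imputed_frames = [pd.concat(parts, ignore_index=True) for parts in completed]
    table = annual_population_biomass(imputed_frames, species_mass, years=years)
    return table, excluded
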