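"""Simulation-based validation: can the estimation pipeline recover the
generating parameters of the synthetic study?

Each replicate simulates a salmon-area landscape (default 55 units x 30
years, the study's scale), runs the full estimation pipeline (filter /
Ricker-impute / aggregate biomass, assemble the design, fit the NB2
random-intercept model) and records the salmon coefficient, its Wald CI,
the dispersion and random-intercept estimates, and — via a small
candidate set over {salmon biomass, pure-noise null predictor} with the
spatial terms fixed — the relative variable importance of the real versus
the null annual signal.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from conflict_ecology.model import fit_candidates, fit_nb2_glmm, model_average
from conflict_ecology.predictors import build_design, gelman_scale
from conflict_ecology.salmon import process_streams
from conflict_ecology.synthetic import (
    LandscapeConfig,
    TruthParams,
    build_design_truth,
    generate_landscape,
    simulate_kills,
    simulate_salmon_streams,
)


def simulate_and_assemble(
    seed: int,
    n_units: int = 55,
    n_years: int = 30,
    truth: TruthParams | None = None,
    n_imputations: int = 10,
    add_null_predictor: bool = True,
):
    """One synthetic dataset pushed through the estimation pipeline.

    Returns the assembled salmon-areas design (optionally augmented with a
    scaled pure-noise annual predictor) and the truth used.
    """
    truth = truth or TruthParams()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(5) % (2**31 - 1)]
    config = LandscapeConfig(
        n_units=n_units,
        year_range=(1980, 1980 + n_years - 1),
        frac_salmon_units=1.0,
        n_subdivisions=2 * n_units,
        seed=seeds[0],
    )
    landscape = generate_landscape(config, truth)
    streams = simulate_salmon_streams(landscape, truth, seeds[1])
    design_truth = build_design_truth(landscape, streams, truth)
    kills = simulate_kills(landscape, design_truth, truth, seeds[2])

    observed = streams.drop(columns=["true_count"])
    biomass, _ = process_streams(
        observed, n_imputations=n_imputations, seed=seeds[3], years=config.years
    )
    design = build_design(
        kills,
        landscape.units,
        landscape.census,
        landscape.climate,
        biomass.data,
        mode="salmon_areas",
        years=config.years,
    )
    if add_null_predictor:
        rng = np.random.default_rng(seeds[4])
        noise = rng.normal(size=len(design.data))
        design.data["null_predictor"] = noise
        design.data["null_predictor"] = design.data.groupby("unit_id")[
            "null_predictor"
        ].transform(gelman_scale)
        design.data = design.data.dropna(subset=["null_predictor"]).reset_index(
            drop=True
        )
    return design, truth, biomass


def single_replicate(
    seed: int,
    n_units: int = 55,
    n_years: int = 30,
    truth: TruthParams | None = None,
    compute_rvi: bool = True,
    n_nodes: int = 15,
) -> dict:
    """Fit one replicate; returns estimates, CI coverage and RVI contrast."""
    truth = truth or TruthParams()
    design, truth, _ = simulate_and_assemble(
        seed, n_units=n_units, n_years=n_years, truth=truth
    )
    full_terms = tuple(design.annual_terms) + tuple(design.spatial_terms)
    fit = fit_nb2_glmm(design, full_terms, n_nodes=n_nodes, seed=seed, n_starts=2)
    b = fit.beta["salmon_biomass"]
    lo, hi = fit.ci("salmon_biomass", 0.95)
    b_true = truth.beta_annual["salmon_biomass"]
    out = {
        "seed": seed,
        "beta_salmon": b,
        "se_salmon": fit.se["salmon_biomass"],
        "covered": bool(lo <= b_true <= hi),
        "sign_match": bool(np.sign(b) == np.sign(b_true)) if b_true != 0 else np.nan,
        "phi": fit.phi,
        "sigma_alpha": fit.sigma_alpha,
        "converged": fit.converged,
    }
    if compute_rvi:
        candidates = [
            tuple(design.spatial_terms),
            ("salmon_biomass",) + tuple(design.spatial_terms),
            ("null_predictor",) + tuple(design.spatial_terms),
            ("salmon_biomass", "null_predictor") + tuple(design.spatial_terms),
        ]
        fits = fit_candidates(design, candidates, n_nodes=n_nodes, seed=seed)
        avg = model_average(fits)
        out["rvi_salmon"] = avg.rvi("salmon_biomass")
        out["rvi_null"] = avg.rvi("null_predictor")
    return out


def recovery_study(
    n_replicates: int = 200,
    seed: int = 0,
    n_units: int = 55,
    n_years: int = 30,
    truth: TruthParams | None = None,
    compute_rvi: bool = True,
) -> pd.DataFrame:
    """Replicated parameter-recovery study; one row per replicate."""
    truth = truth or TruthParams()
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s) for s in ss.generate_state(n_replicates) % (2**31 - 1)]
    rows = [
        single_replicate(
            s, n_units=n_units, n_years=n_years, truth=truth, compute_rvi=compute_rvi
        )
        for s in rep_seeds
    ]
    return pd.DataFrame(rows)


def summarize_recovery(results: pd.DataFrame, truth: TruthParams | None = None) -> dict:
    """Headline recovery metrics for a replicate table."""
    truth = truth or TruthParams()
    b_true = truth.beta_annual["salmon_biomass"]
    out = {
        "n_replicates": int(len(results)),
        "beta_salmon_true": b_true,
        "beta_salmon_median": float(results["beta_salmon"].median()),
        "ci95_coverage_pct": float(100.0 * results["covered"].mean()),
        "sign_match_pct": float(100.0 * results["sign_match"].mean()),
        "phi_median": float(results["phi"].median()),
        "sigma_alpha_median": float(results["sigma_alpha"].median()),
    }
    if "rvi_salmon" in results:
        out["rvi_salmon_median"] = float(results["rvi_salmon"].median())
        out["rvi_null_median"] = float(results["rvi_null"].median())
        out["rvi_salmon_gt_null_pct"] = float(
            100.0 * (results["rvi_salmon"] > results["rvi_null"]).mean()
        )
    return out
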