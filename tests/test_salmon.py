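"""Salmon stage: filtering rules, Ricker maximum likelihood, multiple
imputation, and geometric-mean biomass aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conflict_ecology import filter_series, fit_ricker, impute_series
from conflict_ecology.salmon import (
    FitError,
    RickerFit,
    annual_population_biomass,
    process_streams,
    DEFAULT_SPECIES_MASS,
)
from conflict_ecology.synthetic import _ricker_step


def ricker_series(r, K, sigma, n_years, n0, seed=0, missing=()):
    rng = np.random.default_rng(seed)
    vals = [n0]
    for _ in range(n_years - 1):
        eps = rng.normal(0, sigma) if sigma > 0 else 0.0
        vals.append(vals[-1] * np.exp(r * (1 - vals[-1] / K) + eps))
    counts = [None if y in missing else v for y, v in enumerate(vals)]
    from conftest import make_series

    return make_series(counts)


class TestFilterSeries:
    @pytest.mark.parametrize(
        "missing_years, expect_excluded, expect_reason",
        [
            # 9 scattered missing years out of 30 -> total rule
            (list(range(0, 27, 3)), True, "total>8"),
            # 3 consecutive missing years -> run rule
            ([5, 6, 7], True, "consecutive>=3"),
            # 3 scattered missing years -> retained
            ([5, 6, 10], False, None),
            ([], False, None),
        ],
    )
    def test_rules(self, make_stream_series, missing_years, expect_excluded, expect_reason):
        counts = [None if y in missing_years else 100.0 + y for y in range(30)]
        series = make_stream_series(counts)
        retained, excluded = filter_series(series)
        if expect_excluded:
            assert retained.empty
            assert len(excluded) == 1
            assert expect_reason in excluded["reason"].iat[0]
        else:
            assert excluded.empty
            assert len(retained) == 30

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["stream_id", "species", "unit_id", "year", "count"])
        retained, excluded = filter_series(empty)
        assert retained.empty and excluded.empty

    def test_idempotent_and_order_independent(self, make_stream_series):
        rng = np.random.default_rng(1)
        frames = []
        for i in range(20):
            missing = rng.choice(30, size=rng.integers(0, 12), replace=False)
            counts = [None if y in missing else float(rng.uniform(10, 1000)) for y in range(30)]
            frames.append(
                make_stream_series(counts, stream_id=f"S{i}", species="coho")
            )
        streams = pd.concat(frames, ignore_index=True)
        r1, e1 = filter_series(streams)
        shuffled = streams.sample(frac=1.0, random_state=5).reset_index(drop=True)
        r2, e2 = filter_series(shuffled)
        key = ["stream_id", "species", "year"]
        pd.testing.assert_frame_equal(
            r1.sort_values(key).reset_index(drop=True),
            r2.sort_values(key).reset_index(drop=True),
        )
        r3, e3 = filter_series(r1)
        assert e3.empty
        assert len(r3) == len(r1)


class TestFitRicker:
    def test_exact_recovery_noiseless(self):
        series = ricker_series(0.5, 1000.0, 0.0, 20, n0=200.0)
        fit = fit_ricker(series)
        assert fit.r == pytest.approx(0.5, abs=1e-6)
        assert fit.K == pytest.approx(1000.0, abs=1e-3)
        assert fit.sigma == pytest.approx(0.0, abs=1e-8)

    def test_near_fixed_point_residuals(self):
        rng = np.random.default_rng(0)
        from conftest import make_series

        counts = 1000.0 * (1 + rng.normal(0, 1e-3, size=15))
        fit = fit_ricker(make_series(list(counts)))
        g = np.log(counts[1:] / counts[:-1])
        resid = g - fit.r * (1 - counts[:-1] / fit.K)
        assert np.mean(resid) == pytest.approx(0.0, abs=1e-4)

    def test_too_few_transitions(self, make_stream_series):
        series = make_stream_series([100.0, None, 120.0, None, 130.0])
        with pytest.raises(FitError):
            fit_ricker(series)

    def test_simulation_recovery(self):
        # median r-hat across replicates close to the generating value
        rhats = []
        for seed in range(500):
            series = ricker_series(0.8, 5000.0, 0.3, 30, n0=3000.0, seed=seed)
            fit = fit_ricker(series)
            rhats.append(fit.r)
        assert np.median(rhats) == pytest.approx(0.8, rel=0.10)

    def test_matches_grid_search_oracle(self):
        # the OLS solution beats every point of a brute-force (r, K) grid
        series = ricker_series(0.6, 800.0, 0.25, 25, n0=300.0, seed=3)
        fit = fit_ricker(series)
        n = series["count"].to_numpy()
        g = np.log(n[1:] / n[:-1])

        def negloglik(r, K, sigma):
            resid = g - r * (1 - n[:-1] / K)
            return 0.5 * len(g) * np.log(2 * np.pi * sigma**2) + 0.5 * np.sum(
                resid**2
            ) / sigma**2

        best = np.inf
        for r in np.linspace(0.2, 1.2, 41):
            for K in np.linspace(300, 2000, 69):
                resid = g - r * (1 - n[:-1] / K)
                sigma = max(np.sqrt(np.mean(resid**2)), 1e-9)
                best = min(best, negloglik(r, K, sigma))
        assert -fit.loglik <= best + 1e-9


class TestImputeSeries:
    def test_zero_noise_collapses_to_map(self, make_stream_series):
        series = make_stream_series([500.0, None, 700.0, 800.0, 820.0, 830.0])
        fit = RickerFit(r=0.5, K=1000.0, sigma=0.0, loglik=0.0, n_transitions=4)
        imps = impute_series(series, fit, n_imputations=5, seed=1)
        expected = _ricker_step(500.0, 0.5, 1000.0)
        for imp in imps:
            assert imp["count"].iat[1] == pytest.approx(expected, rel=1e-12)
        # observed values untouched
        assert all(imp["count"].iat[0] == 500.0 for imp in imps)

    def test_seeded_determinism(self, make_stream_series):
        series = make_stream_series([500.0, None, None, 800.0, None, 830.0])
        fit = RickerFit(r=0.5, K=1000.0, sigma=0.3, loglik=0.0, n_transitions=3)
        a = impute_series(series, fit, n_imputations=10, seed=99)
        b = impute_series(series, fit, n_imputations=10, seed=99)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_leading_missing_backfilled_positive(self, make_stream_series):
        series = make_stream_series([None, None, 600.0, 700.0, 750.0, 790.0])
        fit = RickerFit(r=0.5, K=1000.0, sigma=0.0, loglik=0.0, n_transitions=3)
        imps = impute_series(series, fit, n_imputations=3, seed=2)
        for imp in imps:
            assert (imp["count"] > 0).all()
            # zero-noise backfill: applying the map to the backfilled value
            # recovers the next one
            v = imp["count"].to_numpy()
            assert _ricker_step(v[1], 0.5, 1000.0) == pytest.approx(v[2], rel=1e-6)

    def test_imputation_coverage_on_held_out_truth(self):
        # ~90% of held-out cells within 2 across-imputation SDs on the log scale
        rng = np.random.default_rng(10)
        hits = total = 0
        for rep in range(40):
            full = ricker_series(0.8, 5000.0, 0.3, 30, n0=4000.0, seed=1000 + rep)
            truth_vals = full["count"].to_numpy().copy()
            miss = rng.choice(np.arange(1, 30), size=6, replace=False)
            observed = full.copy()
            observed.loc[observed.index[miss], "count"] = np.nan
            fit = fit_ricker(observed)
            imps = impute_series(observed, fit, n_imputations=20, seed=rep)
            mat = np.log(np.array([imp["count"].to_numpy() for imp in imps]))
            mean = mat.mean(axis=0)
            sd = mat.std(axis=0, ddof=1)
            for t in miss:
                total += 1
                if abs(mean[t] - np.log(truth_vals[t])) <= 2 * max(sd[t], 1e-9):
                    hits += 1
        assert hits / total >= 0.90


class TestBiomass:
    def _frame(self, unit_streams):
        rows = []
        for sid, (unit, count) in enumerate(unit_streams):
            rows.append(
                {
                    "stream_id": f"S{sid}",
                    "species": "pink",  # 1.8 kg each; counts chosen to hit biomass
                    "unit_id": unit,
                    "year": 2000,
                    "count": count / DEFAULT_SPECIES_MASS["pink"],
                }
            )
        return pd.DataFrame(rows)

    def test_geometric_mean_two_streams(self):
        table = annual_population_biomass([self._frame([("U1", 100.0), ("U1", 400.0)])])
        assert table.data["biomass_kg"].iat[0] == pytest.approx(200.0, rel=1e-9)

    def test_single_stream_identity(self):
        table = annual_population_biomass([self._frame([("U1", 123.0)])])
        assert table.data["biomass_kg"].iat[0] == pytest.approx(123.0, rel=1e-9)

    def test_geometric_mean_three_streams(self):
        table = annual_population_biomass(
            [self._frame([("U1", 10.0), ("U1", 100.0), ("U1", 1000.0)])]
        )
        assert table.data["biomass_kg"].iat[0] == pytest.approx(100.0, rel=1e-9)

    def test_species_missing_from_mass_table(self):
        frame = self._frame([("U1", 100.0)])
        with pytest.raises(KeyError):
            annual_population_biomass([frame], species_mass={"coho": 3.2})

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_geometric_mean_scales_linearly(self, scale):
        base = self._frame([("U1", 20.0), ("U1", 180.0), ("U1", 64.0)])
        scaled = base.assign(count=base["count"] * scale)
        b0 = annual_population_biomass([base]).data["biomass_kg"].iat[0]
        b1 = annual_population_biomass([scaled]).data["biomass_kg"].iat[0]
        assert b1 == pytest.approx(b0 * scale, rel=1e-9)

    def test_stream_order_invariance(self, small_streams):
        complete = small_streams.rename(columns={"true_count": "c"}).drop(
            columns=["count"]
        ).rename(columns={"c": "count"})
        t1 = annual_population_biomass([complete])
        shuffled = complete.sample(frac=1.0, random_state=3)
        t2 = annual_population_biomass([shuffled])
        pd.testing.assert_frame_equal(
            t1.data.reset_index(drop=True), t2.data.reset_index(drop=True)
        )

    def test_scaled_biomass_mean_zero_sd_half(self, small_streams):
        table, _ = process_streams(
            small_streams.drop(columns=["true_count"]), n_imputations=5, seed=1
        )
        for _, grp in table.data.groupby("unit_id"):
            assert grp["biomass_scaled"].mean() == pytest.approx(0.0, abs=1e-9)
            assert grp["biomass_scaled"].std(ddof=1) == pytest.approx(0.5, abs=1e-9)

    def test_zero_biomass_floored(self, make_stream_series):
        series = make_stream_series([100.0, 0.0, 50.0])
        table = annual_population_biomass([series])
        assert (table.data["biomass_kg"] > 0).all()
        # floored at half the smallest positive stream biomass (50 * 1.8 / 2)
        assert table.data["biomass_kg"].min() == pytest.approx(45.0, rel=1e-9)
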