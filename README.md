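# conflict-ecology

Statistical machinery for studying how marine food supply shapes
human–wildlife conflict on land: annual counts of grizzly bears killed
in conflict with people, modeled as a function of the salmon biomass
returning to each bear population unit's spawning streams.

The package implements the full analysis chain:

1. **Salmon biomass reconstruction** (`conflict_ecology.salmon`) —
   quality-filter stream escapement series, fit a Ricker-logistic
   population model per stream and species, multiply impute missing
   years (proper multiple imputation propagating parameter
   uncertainty), convert counts to biomass via species mean masses, and
   aggregate to an annual geometric-mean biomass per population unit.
2. **Predictor assembly** (`conflict_ecology.predictors`) — late-season
   (on/after July 1) conflict-kill responses per unit-year; rolling
   3-year windows of prior conflict and hunt kills; human density
   attributed from census subdivision overlaps; climate-normal and
   annual temperature/precipitation covariates from gridded points; all
   continuous predictors centred and divided by two standard deviations
   (Gelman scaling) so coefficients are comparable.
3. **Model fitting** (`conflict_ecology.model`) — negative binomial
   (NB2) random-intercept GLMM with a log habitable-area exposure
   offset, fitted by maximum likelihood with adaptive Gauss–Hermite
   quadrature and an analytic (Fisher identity) gradient; AICc model
   averaging over all annual-predictor subsets, with relative variable
   importance (RVI), unconditional standard errors, and translation of
   the salmon coefficient into the percent change in expected conflict
   for a 50% change in salmon biomass.
4. **Summaries** (`conflict_ecology.summaries`) — monthly/seasonal
   tallies, era-aware severe-attack filtering, and quartic-kernel
   density surfaces of kill locations written as ESRI ASCII grids.
5. **Synthetic study system** (`conflict_ecology.synthetic`,
   `conflict_ecology.recovery`) — a seeded generator of landscapes,
   salmon streams, kill and attack records with known parameters, used
   for end-to-end parameter-recovery validation.

A pipeline driver (`conflict_ecology.pipeline`) and a `conflict-ecology`
command line tie the stages together.

## Worked example

Run the whole pipeline on a small synthetic study system and read off
the fitted salmon effect:

```python
import json, pathlib
import pandas as pd
from conflict_ecology.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    data_dir="scratch/demo/data", out_dir="scratch/demo/out",
    mode="salmon_areas", year_range=(1980, 2005), n_units=12,
    frac_salmon_units=1.0, n_imputations=6, seed=20,
)
run_pipeline(cfg)

print(json.dumps(json.loads(
    pathlib.Path("scratch/demo/out/effect.json").read_text()), indent=2))
seasonal = pd.read_csv("scratch/demo/out/seasonal.csv")
print(seasonal[["stratum", "n_total", "n_late", "late_percent"]]
      .to_string(index=False))
```

Output (seed 20; byte-reproducible):

```
{
  "beta_salmon": -0.5839461801550536,
  "sd_avg_log_biomass": 0.12628245892149947,
  "fold": 0.5,
  "percent_change": 396.59292476950696,
  "percent_change_ci95": [
    14.825441593765042,
    2047.6471547445265
  ],
  "rvi_salmon": 0.9343348333839336
}
         stratum  n_total  n_late  late_percent
       all_kills      317     252          79.0
    salmon_areas      317     252          79.0
non_salmon_areas        0       0           NaN
  severe_attacks       74      61          82.0
```

The negative `beta_salmon` (per 2 SD of log salmon biomass) with RVI
0.93 recovers the simulated food-supply effect. The large
`percent_change` is a feature of this synthetic system, not a bug: its
streams fluctuate independently, so the within-unit SD of log
geometric-mean biomass (0.126) is small and a 50% biomass decline is a
many-SD excursion; in real escapement data, where streams covary
strongly, the same formula yields much smaller translated effects.

The effect translation itself is a one-liner:

```python
>>> from conflict_ecology import salmon_effect_percent
>>> salmon_effect_percent(-0.3, 0.5, fold=0.5)  # beta per 2 SD, sd 0.5, halving
23.114440824342227
```

The same pipeline runs from the command line, driven by a YAML config:

```sh
conflict-ecology run-all --config config.yaml
# or stage by stage:
conflict-ecology simulate --config config.yaml
conflict-ecology salmon   --config config.yaml
conflict-ecology design   --config config.yaml
conflict-ecology fit      --config config.yaml --mode salmon_areas
conflict-ecology summarize --config config.yaml
```

With `simulate: false` in the config the pipeline skips the generator
and reads `units.csv`, `census.csv`, `climate.csv`, `streams.csv`,
`kills.csv` and `attacks.csv` from `data_dir` — the re-analysis mode
for externally supplied data.

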