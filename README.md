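# firethresh

Critical vapour-pressure-deficit (VPD) thresholds for forest fire activity:
occurrence modelling, bias-corrected climate projection, and population /
forest-carbon exposure mapping.

## The problem

The moisture content of dead fine fuel on the forest floor gates whether a
forest can burn, and VPD — the gap between saturation and actual vapour
pressure of near-surface air, in kPa — is a direct measure of the
atmosphere's drying power and hence a strong daily predictor of fuel
dryness. For a forest stratum (a biome × regional window), daily fire
occurrence can be modelled against daily-maximum VPD with a logistic
regression

&nbsp;&nbsp;&nbsp;&nbsp;P(fire | VPD = v) = logit⁻¹(β₀ + β₁ v),

and the **fire-activity threshold** is the VPD at which this probability
crosses one half:

&nbsp;&nbsp;&nbsp;&nbsp;VPD_P50 = −β₀ / β₁  (kPa),  SE by the delta method,  CI = ±2·SE.

Counting the days per year on which daily-maximum VPD exceeds VPD_P50 —
under observed climate and under bias-corrected model climate for future
epochs — gives a climatology of *potential fire days*; multiplying the
projected change in that count by population or aboveground-biomass density
gives exposure maps in person-days/year and tonne-days/year.

`firethresh` implements this chain end to end for researchers in landscape
fire ecology and climate-risk assessment, together with a fully seeded
synthetic-data layer (planted logistic fire laws, AR(1) seasonal climate,
affinely distorted "climate-model" series, density rasters with missing-data
holes) so every stage is testable offline against known truth.

## Worked example

Fit the occurrence model on samples drawn from a planted law with
β₀ = −5, β₁ = 2 (true threshold 2.5 kPa):

```python
from firethresh import FireOccurrenceModel, PlantedFireLaw, generate_occurrence_samples

law = PlantedFireLaw(-5.0, 2.0)
samples = generate_occurrence_samples(law, 10_000, seed=42)
result = FireOccurrenceModel.from_dataframe(samples).fit()
print(result.summary())
```

```
Fire occurrence model (binomial GLM, logit link)
========================================================
stratum:             s0
n rows:              10000
converged:           True
beta0 (intercept):   -5.0380  (SE 0.1056)
beta1 (per kPa):      2.0014  (SE 0.0408)
--------------------------------------------------------
VPD_P50 [kPa]:        2.5172  (SE 0.0128)
95% CI (+/-2 SE):    (2.4915, 2.5428)
AUC:                 0.8619
TPR @ p>=0.5:        0.7674
deviance explained:  33.33 %
========================================================
```

The planted 2.5 kPa threshold is recovered to 0.017 kPa, well inside the
±2·SE interval; the AUC of 0.86 says fire days are ranked above non-fire
days by VPD 86% of the time, and the TPR says 77% of fire days are
correctly called at the 50% probability cutoff.

The same objects drive the full pipeline — synthetic world, daily-max VPD at
the time of maximum temperature, presence/quasi-absence sampling with the
5-year burn exclusion, per-stratum fits, quantile-mapping bias correction,
exceedance-day change maps, exposure rasters — from one config:

```bash
firethresh run --config config.yaml
```

with a config like

```yaml
outdir: runs/demo
seed: 1
world: {n_lat: 4, n_lon: 4, years: [2003, 2004, 2005], steps_per_day: 24}
strata:
  - {id: north, lat_rows: [0, 2], biome_group: boreal}
  - {id: south, lat_rows: [2, 4], biome_group: tropical}
```

Each stage can also be run alone (`firethresh simulate|vpd|sample|fit|
bias-correct|exceedance|exposure|validate`); outputs carry the config hash
and stage seeds, reruns are idempotent unless `--force`, and any stage rerun
under the same config and seed is bit-identical.

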