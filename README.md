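# terrattrib

Machine-learning attribution of spatial variation in the **dry-season
vegetation decay rate** to terrain-mediated *secondary water* effects —
groundwater, capillary rise and lateral moisture redistribution that buffer
dryland vegetation against drought after the rains stop.

The package is aimed at ecohydrologists and land-surface modellers who want
a tested, fully synthetic-data-verifiable implementation of this analysis
chain:

1. **Decay rate (λ).**  Per cell and season, daily fractional vegetation
   cover is fitted with the asymptotic exponential
   `v(t) = v_min + (v0 − v_min)·exp(−t/λ)`; λ (days) is the e-folding
   timescale of decay, independent of event amplitude and timing.  Cells
   are kept when the relative standard error of λ is ≤ 1 and ≥ 3 of 16
   seasonal fits converged.
2. **Physical terrain predictors.**  Saxton–Rawls pedotransfer from soil
   composition to wilting point, field capacity, saturation and
   conductivity; plant available water (PAW) and conductivity at field
   capacity (k_FC); and the maximum steady upward capillary flux I_cap at
   1 m above the water table, from the steady-state Richards equation
   `z_max(q) = ∫ dh / (1 + q/K(h))` solved for the flux that reaches the
   prescribed height.
3. **Constrained model.**  λ is modelled with gradient-boosted trees
   (XGBoost) trained on a random 10 % of cells, with monotone constraints
   on every terrain predictor (negative for water table depth and height
   above nearest drainage, positive otherwise) so terrain can only act in
   the physically plausible direction; validation skill is measured with
   Nash–Sutcliffe efficiency.
4. **Grouped SHAP attribution.**  Per-cell SHAP interaction values
   (computed exactly, in double precision, by per-tree subset enumeration)
   are grouped into six additive components — terrain/climate/vegetation
   direct plus terrain×climate, terrain×vegetation, climate×vegetation —
   and normalized by absolute values into the terrain importance
   Φ_terrain ∈ [0, 1], mapped and binned against VRM, water table depth,
   I_cap and annual precipitation.

Because the continental raster stack such an analysis consumes cannot be
redistributed, the package ships a **synthetic landscape generator** with a
known generative model for λ (controllable terrain-attributable variance
share, interaction split, noise, and cross-group confounding), so every
stage is testable as parameter recovery with exact ground truth.

## Worked example

```python
from terrattrib import (GridSpec, SyntheticTruth, generate_landscape,
                        build_feature_table, apply_domain_filters,
                        split_train, fit, nse, interaction_values,
                        group_attribution, normalize_importance)
import numpy as np

truth = SyntheticTruth(seed=42, terrain_share=0.5, interaction_share=0.5,
                       noise_sd=5.0)
bundle = generate_landscape(GridSpec(128, 128), truth)
table = apply_domain_filters(build_feature_table(bundle))
train, valid = split_train(table, 0.10, seed=42)
model = fit(train, table.groups, seed=42)
print("validation NSE:", round(nse(valid["lambda"].to_numpy(),
                                   model.predict(valid)), 3))

cells = table.data.sample(4000, random_state=42).sort_index()
imp = normalize_importance(group_attribution(
    interaction_values(model, cells), table.groups))
print("mean terrain importance:", round(float(np.nanmean(imp.terrain_total)), 3))
```

prints

```
validation NSE: 0.894
mean terrain importance: 0.369
```

i.e. the constrained model explains 89 % of the decay-rate variance on
held-out cells of this landscape, and attributes on average 37 % of its
per-cell output deviation to the terrain group (0.269 direct + 0.100 via
interactions with climate and vegetation) — for a landscape whose true
terrain share of explainable variance is 0.50 under 5 days of noise.
Landscapes generated with terrain shares 0, 0.25, 0.5 and 0.75 recover
mean importances of about 0.02, 0.24, 0.38 and 0.52: strictly ordered,
with the share-0 landscape at the permutation-null floor.

The same pipeline is scriptable: `terrattrib simulate`, `terrattrib
fit-decay` and `terrattrib run --config run.yaml` orchestrate the stages
with a manifest of checksums and headline numbers, and the numbered
drivers under `analysis/` reproduce the tables in `results/`.

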