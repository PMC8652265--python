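# greencool

Spatially explicit urban-greening scenarios and their heat-mitigation
potential.

Urban trees are among the most effective levers against night-time urban
heat, but planners lack tools to ask *where* additional canopy pays off
most at the agglomeration scale. `greencool` simulates that question end
to end on a raster representation of a city: it refines a
land-use/land-cover (LULC) map by fine-scale tree and building cover,
generates stochastic tree-canopy scenarios under three spatial
allocation strategies, simulates night-time air temperature with a
shade/evapotranspiration/albedo cooling model, quantifies the resulting
canopy pattern with landscape metrics, and counts the population exposed
to high temperatures. A synthetic-city generator provides all inputs, so
the whole pipeline runs without any external dataset.

It is aimed at researchers in urban ecology and ecosystem services who
want a self-contained, reproducible sandbox for canopy-allocation
experiments.

## The model

**Refinement.** Each 10 m LULC pixel is coupled with 1 m binary tree and
building masks to compute its cover fractions, which are binned into four
equal intervals (0–25, 25–50, 50–75, 75–100%). A pixel with tree cover
≥ 75% has *high tree canopy cover*: trees with 5 m spherical crowns
spaced 10 m apart form a continuous canopy at that density. The shade
coefficient of a refined class is its tree-bin midpoint (0.125, 0.375,
0.625, 0.875); albedo is interpolated toward the roof albedo by the
building-bin midpoint.

**Scenarios.** Candidate pixels (the six transformable classes, building
cover < 25%, roads only when adjacent to another class, not already
high-canopy) are raised to the highest tree bin for a proportion
p ∈ {12.5, …, 87.5, 100}% of the candidate set, under three strategies:
`random` sampling, `cluster` (greedily transform the candidate with the
most high-canopy Moore neighbours, counts updated dynamically) and
`scatter` (the same, minimizing). 7 proportions × 3 strategies × 10 runs
plus the single deterministic 100% scenario give 211 scenarios.

**Cooling.** Cooling capacity CC = 0.6·shade + 0.2·albedo + 0.2·ETI with
ETI = k_c·ET₀/ET_max (Hargreaves reference evapotranspiration,
ET₀ = 0.0023·R_a·(T_avg+17.8)·√(T_max−T_min)). Near green patches ≥ 2 ha
the heat-mitigation index HM is raised to the exp(−d/d_cool)-weighted
mean CC of the green pixels within d_cool = 100 m. Air temperature is
T = T_ref + (1−HM)·UHI_max, blended by a Gaussian moving average of
radius r_mix = 500 m. T_ref and UHI_max come from the 21.00 station
readings of the day with the largest admissible max–min spread.

**Pattern and exposure.** High-canopy patches (8-connected) are
summarized by PLAND, AREA_MN, SHAPE_MN and ED; the temperature field is
averaged to 100 m census cells and the population of cells strictly above
each threshold (21…26 °C) counts as exposed.

## Worked example

```python
import greencool as gc

inputs = gc.synthesize_inputs(gc.CityBlueprint(seed=0))   # 240x240 @ 10 m
cands  = gc.find_candidates(inputs.refined)
print(cands.total_count)                 # 27191 candidate pixels
print(inputs.params.t_ref, inputs.params.uhi_max)   # 20.54 degC, 5.94 degC

res = gc.run_experiment(inputs, gc.ExperimentDesign(
    proportions=(0.25, 0.5, 0.75), runs_per_config=3, master_seed=0))
df = res.results
print(df.groupby(["proportion", "strategy"])[
    ["t_mean", "area_mn", "exposed_gt_25"]].mean().round(3))
```

prints (abridged):

```
proportion strategy   t_mean  area_mn  exposed_gt_25
0.25       cluster    23.279    4.097        11048.0
           random     23.200    0.118         7191.7
           scatter    23.195    0.043         5559.0
0.50       cluster    23.071    8.862        10350.0
           random     22.984    0.442         2624.3
           scatter    22.972    0.218            0.0
```

Reading: the baseline city simulates at a mean of 23.445 °C with 11 168
of 20 000 inhabitants above 25 °C. Greening 25% of the candidates cools
the mean by ~0.25 °C regardless of strategy (composition dominates), but
*where* the canopy goes decides exposure: scattering the new canopy
through the warm core halves the >25 °C population (5 559), while
clustering it onto the existing forest edge barely helps (11 048).
Clustered allocation grows large patches (AREA_MN 4.1 ha vs 0.04 ha) with
far lower edge density. At 50% greening the scattered scenario removes
>25 °C exposure entirely.

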