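# catscape

Population-level utilization distributions for GPS-tracked outdoor pet
cats — from raw 30-second telemetry fixes to the aggregated intensity
surface a neighbourhood's cats collectively drape over the landscape.

Domestic cats are among the most abundant carnivores anywhere, and their
predation pressure is a population-level phenomenon: what a bird or rodent
experiences is not one cat's home range but the combined intensity of use
of every outdoor cat around it. This package implements the full analysis
chain for mapping that surface from dense GPS tracking of (ideally) all
cats in a neighbourhood:

1. **Preprocessing** (`catscape.tracks`) — four removal rules (elevation
   outside 0–300 m, the first 2 days of deployment, unit-download days,
   estimated horizontal position error ≥ 5000) plus greedy thinning to a
   ≥ 2-min fix interval.
2. **Indoor-activity excision** (`catscape.clustering`) — sequential
   position clusters (running-centroid scan, 10-m radius) whose centroid
   falls on the owner's residence footprint are removed wholesale, leaving
   outdoor-only tracks.
3. **Individual utilization distributions** (`catscape.bbmm`) — a Brownian
   bridge movement model (BBMM) per cat, statsmodels-style:
   `BrownianBridge(track).fit()` returns a results object carrying the
   motion-variance estimate and building UD rasters and volume-contour
   home ranges.
4. **Aggregation** (`catscape.population`) — individual UDs are aligned to
   one grid, each re-scaled to sum to the cat's outdoor weight
   *wᵢ* (mean fraction of a 24-h day tracked outdoors on days with data),
   and summed — deliberately *not* renormalised, so surfaces are
   comparable between populations in magnitude as well as shape — plus the
   spatial summary statistics (intensity fold range, near-home intensity
   ratio, distance-to-home statistics, developed/other land-cover
   partition).
5. **Synthetic populations** (`catscape.simulate`) — a generator with
   known ground truth (home-anchored Ornstein–Uhlenbeck excursions, indoor
   bouts, GPS noise, planted outliers, missing days) so every stage is
   testable without any field data.

## The model

Between consecutive fixes **z**ᵢ, **z**ᵢ₊₁ separated by time *T*, the
animal's position at fraction α ∈ (0, 1) of the gap is modelled as
bivariate normal with mean **z**ᵢ + α(**z**ᵢ₊₁ − **z**ᵢ) and per-axis
variance

σ²(α) = *T* α(1−α) σ²ₘ + (1−α)² δ² + α² δ²,

where σ²ₘ is the Brownian motion variance and δ the GPS location error.
The UD is the Δt-weighted average of these bridge densities over all fix
pairs (gaps longer than a maximum lag, default 60 min, are not bridged).
σ²ₘ is estimated by leave-one-out maximum likelihood on alternating fixes;
see `docs/methods.md` for the error-model detail that makes this estimator
consistent. Home ranges are volume contours: the smallest cell set holding
50% (core), 95% (home range) or 99% of UD mass.

## Worked example

```python
from catscape import SimConfig, simulate_population, run_pipeline, PipelineConfig

pop = simulate_population(SimConfig(n_cats=12, seed=1))
result = run_pipeline(pop.tracks, pop.cats, landcover=pop.landcover,
                      config=PipelineConfig(location_error=5.0))

print(result.per_cat["cat003"].results.summary())
```

```
Brownian Bridge Movement Model Results
==============================================
cat id                                  cat003
n fixes                                   5193
n leave-one-out triplets                  2576
location error delta (m)                  5.00
max lag (s)                               3600
sigma_m^2 (m^2/s)                     0.081084
sigma_m^2 (m^2/min)                     4.8651
log-likelihood                      -16953.702
==============================================
```

The fitted motion variance (≈ 4.9 m²/min; this cat's simulated truth is
5.4) controls how widely the bridges spread between fixes. Per-cat and
population summaries:

```python
cols = ["cat_id", "outdoor_weight", "area_ha_50", "area_ha_95",
        "mean_distance_home_m", "frac_fixes_within_50m"]
print(result.summary_per_cat[cols].head(4).to_string(index=False))
```

```
cat_id  outdoor_weight  area_ha_50  area_ha_95  mean_distance_home_m  frac_fixes_within_50m
cat000        0.388158        0.67        2.52             50.291569               0.535658
cat001        0.304816        0.53        2.26             47.360617               0.591701
cat002        0.325479        0.72        2.48             52.026980               0.504531
cat003        0.353802        0.27        1.03             32.554827               0.870618
```

Each cat spends most of its outdoor time within tens of meters of home
(core areas of a fraction of a hectare inside few-hectare home ranges).
The population surface sums the weighted UDs:

```python
for k, v in result.summary_population.items():
    print(f"{k:40s} {v:10.3f}")
```

```
n_cats                                       12.000
total_weight                                  3.960
catscape_area_99_ha                          20.170
intensity_fold_range_99                      45.023
near_home_intensity_ratio                     3.171
frac_area_outside_developed                   0.093
frac_intensity_outside_developed              0.026
```

The catscape's total mass equals Σ wᵢ = 3.96 (mass conservation through
the whole chain), intensity varies 45-fold across the 99% contour, is
3.2× higher within 50 m of a home than 50–100 m away, and although 9% of
the contour's area lies outside the developed polygon, only 2.6% of the
intensity does — cat pressure concentrates tightly around homes.

`run_pipeline(..., out_dir="results/")` additionally writes
`catscape.asc` (ESRI ASCII grid), per-cat UDs, `contours.geojson`,
`summary_per_cat.csv`, `summary_population.csv` and a `manifest.yaml`
recording every default used.

The same pipeline is available from the shell:

```sh
catscape simulate --n-cats 12 --seed 1 --out-dir sim
catscape run --fixes sim/fixes.csv --homes sim/homes.geojson \
    --landcover sim/landcover.geojson --meta sim/meta.yaml --out-dir results
```

with `catscape filter`, `catscape declutter` and `catscape bbmm` exposing
the individual stages.

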