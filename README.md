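# nichekit

Niche-partitioning analyses for sympatric mammal assemblages, built for the
kind of study where a handful of radio-collared carnivores (ocelots,
crab-eating foxes, brown-nosed coatis, ...) and a camera-trap grid have to
answer three questions at once: *where* does each animal live, *which
habitats* does it pick, and *when* is it active?

The package implements the complete analysis chain on three niche axes:

* **Space** — per-individual utilization distributions (UDs) by fixed
  bivariate Gaussian kernel with per-axis direct plug-in bandwidths;
  95%/50% highest-density isopleth home ranges; MCP-100% areas and
  accumulation curves; and the two UD overlap indices
  `PHR_ij = ∫_{HR_i} UD_j dA` (probability of *j* being inside *i*'s home
  range) and `UDOI = A_ij ∬_{HR_i∩HR_j} UD_i · UD_j dA` (0 = disjoint, 1 =
  two uniform UDs in full overlap, > 1 for concentrated joint use).
* **Habitat** — compositional analysis of habitat selection at second order
  (home range vs study area, "Type II") and third order (locations vs home
  range, "Type III"). Each individual contributes the log-ratio difference
  vector `y_k = ln(U_k/U_r) − ln(V_k/V_r)`; non-random use is tested with
  Wilks' `Λ = |Σ(y−ȳ)(y−ȳ)'| / |Σ yy'|`, `χ² = −N ln Λ` on `D−1` df, with
  an exact sign-flip randomization alternative, plus pairwise paired-*t*
  ranking matrices.
* **Time** — detection times rescaled to *sun time* (sunrise ↦ 06:00,
  sunset ↦ 18:00, light and dark periods each split into 12 equal hours;
  NOAA solar equations built in), von Mises circular kernel densities with
  likelihood-selected concentration, 95%/50% highest-density activity
  isopleths, and pairwise percent overlap of active periods.

A first-class synthetic-data module generates patchy five-class landscapes,
habitat-weighted bivariate-normal telemetry, and activity-thinned camera
streams with *known* ground truth (analytic ellipse areas, selection
weights, true diel densities), so every estimator ships with
parameter-recovery tests and no field data are required.

## Worked example

```python
import nichekit as nk

sim  = nk.simulate_study(nk.default_study_config(seed=1))
locs = sim["telemetry"]                      # 20 LocationSets, 3 species

res = nk.KernelHomeRange(locs[0], cell_size=50.0).fit()
print(res.summary().round(2).to_string(index=False))
```

```
animal_id  n_locations  h_x_m  h_y_m  mcp100_km2  ud50_km2  ud95_km2
      OC1           81 490.52 547.93       18.32      6.24     24.72
```

81 daily fixes give plug-in bandwidths of ~0.5 km per axis and a 95%
kernel home range of 24.7 km²; the generator's analytic 95% ellipse for
this individual is 24.3 km², so the estimate is within 2%.

```python
om = nk.species_overlap_matrix(locs, level=0.95)
print(om.to_table().to_string())
```

```
             ocelot          fox        coati
ocelot  95.0 (1.67)  95.6 (0.73)  95.7 (0.45)
fox     72.8 (0.73)  95.0 (1.23)  69.2 (0.39)
coati   49.3 (0.45)  55.9 (0.39)  95.0 (1.58)
```

Rows own the home range: the column species' UD is integrated over it, so
the diagonal is the isopleth level (95.0) and PHR is asymmetric — nearly
all of the small-ranged fox and coati mass sits inside the wide ocelot
ranges (95.6, 95.7) while the reverse shares are lower (72.8, 49.3). UDOI
(in parentheses) is symmetric.

```python
hmap    = sim["landscape"]
members = [ls for ls in locs if ls.species == "coati"]
hrs     = {ls.animal_id: nk.isopleth(nk.estimate_ud(ls, allow_few=True), 0.95)
           for ls in members}
comps   = [nk.composition_type3(ls, hrs[ls.animal_id], hmap) for ls in members]
print(nk.CompositionalSelection(comps, zero_replacement=1e-4).fit().summary())
```

```
Type III compositional test: lambda = 0.192; chi2(4) = 11.553; p = 0.021

Pairwise selection (paired t, p in parentheses); higher rank = stronger selection:
                     forest scrub-savanna     grassland         ponds Ranking
savanna        2.208 (0.07)  2.765 (0.03)  2.951 (0.03)  1.649 (0.15)       4
forest                       0.392 (0.71)  0.662 (0.53)  1.190 (0.28)       3
...
```

The simulated coatis carry a savanna selection weight of 2; the fitted
analysis rejects random use (p = 0.021) and ranks savanna on top — the
weight the generator put in is what the analysis gets out.

The command-line interface mirrors the library
(`nichekit simulate|homerange|overlap|habitat|activity|all`), e.g.

```sh
nichekit simulate --seed 1 --out study/
nichekit homerange --locations study/telemetry.csv --out hr/
nichekit all --seed 1 --out full_run/
```

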