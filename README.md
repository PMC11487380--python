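# carbonscape

Regional land-use/land-cover (LULC) change analysis and terrestrial
carbon-stock accounting on categorical rasters, built around the workflow
used for Mediterranean regional studies such as Calabria (Italy):

1. **Preprocessing** — clip categorical land-cover rasters to an area of
   interest and reclassify the 44 CORINE Land Cover (CLC) level-3 classes
   into 7 IPCC-style categories (Settlement, Crop land, Forest land,
   Grassland, Wetland, Water body, Other land).
2. **Prediction** — estimate per-period transition probability matrices
   `P` by cross-tabulating map pairs, average them, and forecast a future
   map with a CA–Markov model: Markov quantity targets `n' = nᵀP` allocated
   spatially by a 5×5 contiguity filter over several cellular-automata
   iterations. Predictions are validated with the agreement/disagreement
   decomposition (chance, quantity, stratum, grid cell) and the kappa
   family `Kno`, `Kstd`, `Kloc`, `Klocstrata`.
3. **Assessment** — per-class carbon pools (above-ground `CAG`,
   below-ground `CBG`, soil `CSOIL`, dead organic matter `CDOM`, Mg/ha)
   turn each map into a carbon storage map
   `C = A·(CAG+CBG+CSOIL+CDOM)` per cell; a multi-year ledger reports
   stored carbon, sequestration `S = C_T2 − C_T1`, CO₂ equivalents
   (`× 44/12`) and economic value (price `V` EUR/Mg C, annual discount
   rate `r`%, price change `c`%):

   `value = V·s/(q−p) · Σ_{t=0}^{q−p−1} [(1+r/100)(1+c/100)]^{−t}`

A synthetic-landscape generator produces multi-year categorical raster
series with known Markov dynamics and controllable spatial autocorrelation,
so the entire pipeline runs and is testable with no data download.

The default parameter tables shipped in `carbonscape/data/` (reclass map,
averaged transition matrix, forest scaling factors, crop/wetland pools, the
7-class carbon pool table, per-year class areas and validation components)
are those of the Calabria 2000–2024 study region.

## Worked example

```python
import carbonscape as cs

# synthetic 4-date series, 7 classes, known dynamics
cfg = cs.SyntheticConfig(rows=120, cols=120, seed=7)
series = cs.generate_series(cfg)          # [('2000', raster), ... ('2018', raster)]

# estimate and average the transition matrices
mats = [cs.to_probabilities(cs.cross_tabulate(r1, r2), period=f"{y1}-{y2}")
        for (y1, r1), (y2, r2) in zip(series, series[1:])]
avg = cs.average_matrices(mats)

# CA-Markov forecast of the next date and its validation against a reference
pred = cs.predict(series[-1][1], avg, cs.PredictionConfig(iterations=6, seed=1))
ac = cs.agreement_components(cs.confusion_matrix(pred, series[-1][1]))
print(cs.kappa_set(ac))

# carbon ledger from the shipped Calabria area and pool tables
from importlib import resources
import pandas as pd
df = pd.read_csv(resources.files("carbonscape.data") / "calabria_areas.csv")
areas = [cs.AreaTable.from_areas(cs.ipcc7_scheme(),
                                 g.set_index("class_code").loc[range(1, 8), "area_km2"],
                                 year=str(y))
         for y, g in df.groupby("year")]
ledger = cs.build_ledger(areas, cs.default_pool_table())
print(ledger.years)
```

which prints (storage in Mg C, value in million EUR at 200 EUR/Mg):

```
   year    stored_Mg  stored_value_MEUR
0  2000  167359521.0         33471.9042
1  2006  166395849.0         33279.1698
2  2012  164606769.0         32921.3538
3  2018  164812989.0         32962.5978
4  2024  164205831.0         32841.1662
```

i.e. the region stored ≈167.4 Tg C in 2000, declining to ≈164.2 Tg C by
2024; `ledger.periods` adds per-period sequestration, CO₂ equivalence and
the discounted value of each change.

The same stages are available from a CLI
(`carbonscape simulate|reclassify|transitions|predict|validate|carbon|ledger|run`),
with `run` driving the whole pipeline from a TOML config file.

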