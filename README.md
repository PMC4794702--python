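# droughtwue

Drought's effect on ecosystem water-use efficiency, as a tested analysis
pipeline.

Ecosystem water-use efficiency, WUE = GPP/ET (g C per kg H₂O), couples the
carbon and water cycles: gross primary production (GPP) is the carbon an
ecosystem fixes, evapotranspiration (ET) the water it spends.  Whether a dry
year raises or lowers WUE depends on which flux is more sensitive to water
availability — in arid ecosystems extra water mostly feeds soil evaporation
(ET-dominated, so WUE *rises* in drought), while in semi-arid and sub-humid
grasslands, croplands and savannas productivity responds faster than ET
(GPP-dominated, so WUE *falls* in drought), and humid ecosystems barely
respond.  `droughtwue` implements the full chain needed to test this at
site or grid scale:

- **Penman PET** (open-water 1948 combination equation) and the wetness
  index WI = P/PET with UNEP aridity classes;
- a complete **Palmer Drought Severity Index** engine (two-layer soil
  water balance, CAFEC coefficients, climatic characteristic K, Z-index,
  three-track spell recursion with backtracking), driven by Penman PET;
- **annual WUE**, linear detrending, Pearson/F-test correlation of WUE
  with a drought index, and boxplot summaries stratified by aridity zone
  or biome;
- the **GPP-vs-ET dominance** classification from mean-normalised
  regression slopes;
- the **drought memory effect**: WUE_t = a·D_t + b·D_{t−1} + c, with
  hierarchical partitioning (Shapley decomposition of R²) and an AIC
  improvement test (ΔAIC > 2);
- a **synthetic generator** producing regime-structured monthly climate
  and flux series, so the whole chain is testable without any downloads.

Key stages are scikit-learn-style estimators (`PalmerDroughtIndex`,
`Detrender`, `DominanceClassifier`, `DroughtMemoryRegression`) with plain
functions underneath.  See `docs/methods.md` for model details and
assumptions.

## Worked example

Run the synthetic-grid workflow (10 cells per regime, 30 years):

```python
from droughtwue import RunConfig, run_pipeline

bundle = run_pipeline(RunConfig(out_dir="demo", seed=1,
                                cells_per_regime=10, n_years=30))
print(bundle["strata"].round(3))
```

```
                     median    q25    q75    min    max  count
stratum
arid                 -0.835 -0.863 -0.795 -0.875 -0.686     10
semi_arid_sub_humid   0.839  0.831  0.862  0.762  0.892     10
humid                 0.110 -0.148  0.148 -0.246  0.422     10
```

Each row summarises the per-cell Pearson correlation r between detrended
annual WUE and the detrended wetness index: arid cells are strongly
negative (WUE rises in drought), semi-arid/sub-humid cells strongly
positive, humid cells near zero — the regime signature the generator
prescribes and the analysis recovers.  Per-cell statistics land in
`demo/locations.csv`; one arid cell reads

```
zone                       arid
r                     -0.868949
dominant                     ET
a                     -11.45039
b                      5.814209
indep_previous_pct    33.626755
improved                   True
```

i.e. the cell is ET-dominated, and the previous-year drought coefficient b
opposes the current-year coefficient a in sign, with the lag carrying ~34%
of the explained variance and the two-year model a clear AIC improvement.

The same stages are available from the shell:

```bash
droughtwue generate --cells-per-regime 5 --years 30 --seed 1 --out grid.nc
droughtwue wetness   --input site.csv
droughtwue pdsi      --input site.csv --awc 152.4
droughtwue correlate --input site.csv
droughtwue memory    --input site.csv
droughtwue run --out results_dir --cells-per-regime 10 --years 30 --seed 1
```

`site.csv` is a monthly table with columns `year, month, precip_mm, tair_c,
rn_mj_m2_d, ea_kpa, wind_m_s, gpp_gc_m2, et_mm`.

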