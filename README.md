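# paleocvd

Climate seasonality and predictability analysis at dated occupation
sites. The package turns a gridded climate time-cube (1,000-year steps)
and a table of dated archaeological occupations into:

- **per-occupation climate values** (mid-age, min, max across each date
  range) for the bioclimatic variables bio01/bio04/bio12/bio15 and NPP,
  with 3×3 land-cell ("directions = 8") buffering and nearest-land
  relocation;
- **regional comparison statistics**: Mann–Whitney U and Ansari–Bradley
  tests, coefficients of variation, a 1000-iteration dating-uncertainty
  sensitivity permutation, and a space-time background resampling null;
- **a change/variability decomposition (CVD)** of per-site climate
  series: singular spectrum analysis (embedding dimension M = 23
  slices, one precession cycle) of the detrended, z-scored series, a
  frequency-domain white-noise criterion selecting the smallest number
  of leading components whose removal leaves a noise-consistent
  residual, and a percent-variance split whose "variability" share
  serves as an unpredictability proxy.

A synthetic-data module generates climate cubes and occupation tables
with known ground truth (precession cycle with hemisphere-inverted
phase, longer "change" cycles, per-cell noise fractions, monthly stacks
exactly consistent with the emitted bio variables), so every stage is
testable end-to-end without external downloads.

## Layout

| module | contents |
| --- | --- |
| `paleocvd.occupations` | inventory reading/validation, date-range protocol, dedup, site spans |
| `paleocvd.bioclim` | bio01/bio04/bio12/bio15 from monthly climatologies |
| `paleocvd.extraction` | `ClimateCube` (netCDF I/O), cell location, nearest-land relocation, buffered series extraction |
| `paleocvd.cvd` | detrend/z-score, SSA, periodogram, white-noise test, CVD |
| `paleocvd.regional_stats` | the two tests, CV, sensitivity permutation, background resampling |
| `paleocvd.synthetic` | ground-truth cube + occupation generator |
| `paleocvd.pipeline`, `paleocvd.cli` | report orchestration and the `paleocvd` CLI |

## CLI

```sh
# generate a synthetic cube + occupation table with ground truth
paleocvd simulate --seed 0 --out sim/

# full pipeline: occupation report + predictability report
paleocvd run-all --cube sim/cube.nc --occupations sim/occupations.csv \
    --seed 1 --n-iter 1000 --out run/

# individual stages
paleocvd extract --cube sim/cube.nc --occupations sim/occupations.csv \
    --variable bio01 --out series.csv
paleocvd cvd --series series_one.csv --m 23 --alpha 0.05
paleocvd compare --cube sim/cube.nc --occupations sim/occupations.csv
paleocvd sensitivity --cube ... --occupations ... --n-iter 1000 --seed 0 --out s.json
paleocvd background --cube ... --occupations ... --region EAST \
    --region-box 30 55 -9 20 --out b.json
paleocvd bioclim --monthly-cube monthly.nc --out bio.nc
```

Region-box defaults used throughout: eastern Africa (30, 55, −9, 20)
and northwestern Africa (−15, 35, 18, 39), as (lon_min, lon_max,
lat_min, lat_max).

Cube layout: netCDF with dims `(time, lat, lon)`, time in integer ka BP
at step 1, variables `bio01 bio04 bio12 bio15 npp` and a `mask`
variable (1 = land); sea cells are NaN. An adapter hook
(`paleocvd.extraction.pastclim_adapter`) documents the conversion point
for external reconstruction exports; it is intentionally not
implemented.

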