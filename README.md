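# aircloud

Cloud-model assessment of urban air quality.

Daily pollutant monitoring produces noisy, skewed concentration series, yet
regulatory reporting wants a single qualitative level per month — "Good",
"Moderate", "Lightly Polluted" and so on. `aircloud` bridges that gap with
the **normal cloud model**: each qualitative level and each month of data is
summarised by three numerical characteristics

- **Ex** — expectation, the most representative concentration of the concept,
- **En** — entropy, the spread of concentrations the concept accepts
  (its fuzziness),
- **He** — hyper-entropy, the uncertainty of En itself (the "thickness" of
  the cloud of sampled drops).

The package is aimed at environmental-health analysts working with Chinese
daily air-quality data (PM2.5, PM10, SO2, NO2, O3 in µg/m³; CO in mg/m³)
graded under GB 3095-2012 / HJ 633-2012, but the grading table is a plain
JSON document and can be swapped for any banded standard.

## What it computes

1. **Standard clouds.** Each regulatory concentration band [Cmin, Cmax]
   becomes the cloud (Ex, En, He) = ((Cmin+Cmax)/2, (Cmax−Cmin)/6, k·En)
   with k = 0.1 by default.
2. **Backward cloud generator.** From daily values x₁…xₙ:
   Ex = x̄, En = √(π/2)·(1/n)Σ|xᵢ−x̄|, He = √|S²ₙ₋₁ − En²|.
3. **Classification.** The similarity of an assessed cloud to level j's
   standard cloud is λⱼ = exp(−(Ex−Exⱼ)²/(2Enⱼ²)); the maximum-membership
   level is the quantitative result, and the pair of levels whose standard
   expectations bracket Ex is the qualitative reading.
4. **IAQI / AQI.** Exact piecewise-linear interpolation of each
   concentration against the index breakpoints (50/100/150/200/300); the
   daily AQI is the maximum sub-index, and the month's AQI series gets its
   own cloud and level.
5. **Grey relational validation.** An independent classifier: dimensionless
   monitoring vector dⱼ = aⱼ/b₁ⱼ, coefficients
   ξᵢⱼ = (Δmin + ρΔmax)/(|dⱼ−fᵢⱼ| + ρΔmax) with ρ = 0.5, level = argmax per
   indicator, reported alongside the cloud levels with a concordance count.

## Worked example

The packaged fixture is the Shenyang November 2016 daily table (30 days).

```python
import aircloud as ac

table = ac.default_grading_table()
standards = ac.build_standard_set(table, k=0.1)
daily = ac.load_shenyang_november()
result = ac.assess_month(daily, standards, table)

for name, ia in result.indicators.items():
    ex, en, he = ia.cloud.as_tuple()
    print(f"{name:6s} cloud=({ex:7.2f}, {en:6.2f}, {he:6.2f})  level={ia.level}"
          f"  bracket={ia.bracket}")
ex, en, he = result.aqi.cloud.as_tuple()
print(f"AQI    cloud=({ex:7.2f}, {en:6.2f}, {he:6.2f})  level={result.aqi.level}"
      f"  lambda2={result.aqi.similarity.lambdas[1]:.4f}")
print("grey levels:", result.gra.levels,
      f" concordance {result.concordance.agree_count}/{result.concordance.total}")
```

prints

```
PM2.5  cloud=(  73.50,  39.93,  23.36)  level=2  bracket=(2, 3)
PM10   cloud=( 108.45,  48.57,  29.08)  level=2  bracket=(2, 3)
SO2    cloud=(  71.33,  29.07,  12.65)  level=2  bracket=(1, 2)
CO     cloud=(   1.01,   0.38,   0.08)  level=1  bracket=(1, 2)
NO2    cloud=(  48.46,  11.17,   2.21)  level=2  bracket=(1, 2)
O3     cloud=(  57.90,  12.81,   6.10)  level=1  bracket=(1, 2)
AQI    cloud=(  99.59,  47.93,  27.30)  level=2  lambda2=0.0129
grey levels: (2, 2, 2, 1, 2, 1)  concordance 6/6
```

Reading it: PM2.5's monthly cloud sits between the Moderate and Lightly
Polluted standard clouds (bracket 2–3) and classifies as level 2
(Moderate); CO and O3 are Good; the AQI cloud (99.59, 47.93, 27.30) is
Moderate with similarity 0.0129 to the Moderate index standard; the grey
relational classifier agrees on all six indicators.

## Command line

```
aircloud assess  month.csv --out report.json --plot-dir pics/
aircloud series  jan.csv feb.csv ... --out levels.csv
aircloud aqi     month.csv
aircloud gra     month.csv
aircloud simulate --year 2017 --month 1 --seed 42 --out jan.csv
aircloud plot    month.csv --indicator PM2.5 --out pm25.png
```

`simulate` generates synthetic daily series with realistic seasonal
structure (winter-peaking PM2.5/SO2/NO2, summer-peaking O3) for pipelines
whose real archives cannot be redistributed. Defaults for k, ρ, the seed
and the grading-table path can live in a YAML/JSON config (`--config`).

## Acceptance script

`scripts/acceptance.py` re-derives the package's headline quantities from
scratch — standard-cloud cells from the packaged grading table, backward
clouds and the daily-AQI cloud from the packaged November daily table, the
Moderate similarity and the grey dimensionless vector — and writes them as
JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
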