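# Methods

## The cloud model

A qualitative concept over a concentration axis is represented by a *normal
cloud*: a population of random drops (x, μ) governed by three numbers. Ex
is the centre of the concept; En both measures the concept's fuzziness and
sets the dispersion of drops; He is the second-order uncertainty — the
standard deviation of the per-drop entropy draw — and controls how thick
the (x, μ) scatter is at a fixed x. The model deliberately mixes fuzziness
(membership is not 0/1) with randomness (membership at a given x is itself
a random variable).

**Forward generator.** For each drop: En′ ~ N(En, He), x ~ N(Ex, En′),
μ = exp(−(x−Ex)²/(2En′²)). Two numerical choices are ours:

- En′ draws that come out ≤ 0 (possible whenever He > 0) are rejected and
  redrawn; the rejection count is kept on the sample. Truncating at a small
  positive value instead would bias drops toward Ex; rejection keeps μ
  well-defined without that bias.
- En = 0 input produces a flagged degenerate sample (all drops at Ex with
  μ = 1) rather than an error, because constant observed data is legal
  downstream and still needs a renderable cloud.

**Backward generator.** A first-order moment estimator:
Ex = x̄; En = √(π/2) · mean|xᵢ − x̄| (the absolute central moment of a
normal scaled to its standard deviation); He = √|S²ₙ₋₁ − En²|. The absolute
value inside the root guards near-constant or light-tailed samples where
the sample variance falls below En²; when it fires, the estimate carries a
`clipped` flag. The variance uses divisor n−1 and the mean absolute
deviation divisor n — this mixed convention is what reproduces published
monthly characteristics from raw daily tables, so it is frozen. The
fourth-moment backward variant found elsewhere in the cloud-model
literature is deliberately not implemented.

**Classification.** Similarity to level j's standard cloud uses only the
expectations and the standard entropy: λⱼ = exp(−(Ex−Exⱼ)²/(2Enⱼ²)). The
assessed level is the arg-max (maximum membership principle); exact ties
break toward the more severe level — in a health-advisory setting the
protective reading is the defensible default. λ is reported at full
precision for every level; published reports often print small values as 0.
Alongside the arg-max level, the pipeline reports the *qualitative bracket*:
the pair of levels whose standard expectations enclose Ex, encoding the
visual "falls between Moderate and Lightly Polluted" reading of a cloud
picture reproducibly.

## Standard clouds and the grading table

A band [Cmin, Cmax] maps to ((Cmin+Cmax)/2, (Cmax−Cmin)/6, k·En). The /6
places the band edges at ±3 En (the natural bilateral-constraint choice);
k defaults to 0.1 and should stay ≤ 1/3 (a warning fires beyond that).
The packaged table is the Chinese daily grading standard: five levels for
PM2.5, PM10, SO2, NO2, O3 (µg/m³) and CO (mg/m³ — some printed versions of
the table mislabel CO's unit as µg/m³, but the 2–36 band values are only
consistent with mg/m³), plus the index scale with upper limits
50/100/150/200/300. Bands are contiguous from 0, validated on load.

## IAQI and AQI

IAQI is the exact linear interpolation of a concentration onto the index
band matching its concentration band, with band membership half-open
(BP_Lo, BP_Hi] and 0 included in band 1 so that every breakpoint maps to
its index breakpoint uniquely. The daily AQI is the maximum IAQI over the
six pollutants. Two deliberate choices:

- **No rounding by default.** The national technical regulation ceils the
  index to an integer, but exact interpolation is what reproduces published
  index-cloud characteristics; an optional `rounding=True` mode applies the
  ceiling for regulatory-style output.
- **Above-scale extrapolation.** Concentrations beyond the top breakpoint
  extrapolate linearly on the last segment and set an `above_scale` flag;
  clamping at 300 would silently discard information on extreme days.

## Grey relational validation

The cross-check feeds the *same* monthly expectations into an independent
classifier: a = per-indicator backward-cloud expectations, b = the standard
clouds' expectation matrix. After dividing each column by its level-1 entry,
ξᵢⱼ = (Δmin + ρΔmax)/(|dⱼ−fᵢⱼ| + ρΔmax) with Δmin/Δmax global over the
whole matrix and ρ = 0.5 (configurable); each indicator's level is the row
maximising ξ, ties again toward severity. If every distance is zero the
matrix is all ones and flagged degenerate rather than an error. The monthly
report counts per-indicator agreement between cloud and grey levels.

## Pipeline determinism

Estimation, classification, IAQI/AQI and the grey stage involve no
sampling; a monthly assessment is a pure function of the daily table and
the constants (k, ρ). Forward generation appears only in rendering, where
every cloud gets an independent seeded substream. When a month is supplied
as already-estimated characteristics instead of raw days (the supported
input for published monthly tables), the AQI and grey stages are marked
unavailable rather than imputed from the characteristics.

Seasonal summaries compare meteorological winter (December–February) with
summer (June–August) mean levels; the underlying qualitative claim
("higher in winter") does not fix the month sets, so we state ours.

## Synthetic data

The generator emulates a northern Chinese industrial city's daily series at
monthly resolution: each indicator is log-normal around a seasonally
modulated baseline, x = baseline · exp(A·cos(2π(m−peak)/12)) · exp(σZ).
Defaults (chosen once, from the magnitudes of the Shenyang 2016–17 monthly
expectations): PM2.5 45 µg/m³ (σ 0.45, A 0.5, winter peak), SO2 35 (σ 0.45,
A 0.9, winter), NO2 40 (σ 0.30, A 0.3, winter), O3 85 (σ 0.35, A 0.45,
summer peak), PM10 95 and CO 0.95 flat. Generation is bit-reproducible
given (seed, year, month), with an independent substream per month.

What the generator does **not** emulate: day-to-day autocorrelation
(pollution episodes span several days; synthetic days are i.i.d. within a
month), cross-pollutant correlation (real PM2.5 and PM10 are strongly
coupled), and heavy-tail episodes beyond log-normal. A green pipeline test
on synthetic data therefore establishes that the machinery is correct and
seasonally ordered levels emerge, not that the generator is a statistical
twin of any monitoring archive; all numerical reproduction claims rest on
the packaged real November table and the published monthly characteristics.

## Known limitations

- Only five grading levels are modelled; the 300–500 index range is handled
  by the above-scale flag, not a sixth band.
- O3 is taken as the daily summary value; no 8-hour/1-hour averaging logic.
- Normal clouds only — no half or trapezoidal clouds, no multi-dimensional
  clouds.
- The similarity uses the assessed expectation only; two clouds with equal
  Ex but very different En/He classify identically. This is inherent to the
  expectation-based similarity, and is why the report carries En, He and the
  qualitative bracket alongside the level.
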