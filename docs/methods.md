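# Methods

## Two-layer water-cloud model of the panicle canopy

The canopy is treated as two homogeneous "clouds" of water droplets: a
panicle (ear) layer of height `h1` above a stem-and-leaf layer of height
`h2`. Each layer's unit-volume water content is estimated from destructive
sampling as `W = (m_wet − m_dry)·n / h` (kg/m³) with `n` the plant density;
the radar model only depends on the areal water `W·h` (kg/m²).

The forward model in linear power is

```
sigma0 = C·(1 − tau²) + sigma0_soil·tau²,   tau² = exp(−2D·(W1h1 + W2h2)/cosθ)
```

with `C` the volume-scattering asymptote, `D` the attenuation per unit
areal water and `sigma0_soil = A·exp(B·ms)` a bare-soil background.
Soil–canopy multiple scattering is neglected: at Ku band almost nothing
reaches the ground and back. For flooded paddies the background is a
constant water-surface return `sigma0_bg`, giving the equivalent form

```
sigma0 = C + (sigma0_bg − C)·exp(−2D·(W1h1 + W2h2)/cosθ)
```

which is analytically invertible: with `b = cosθ/(2D)` and
`a = b·ln(C − sigma0_bg)`,

```
W1h1 + W2h2 = a − b·ln(C − sigma0),  valid for sigma0 < C.
```

Assumptions worth keeping in mind: layers are internally homogeneous,
attenuation is exponential in areal water with a single `D` shared by both
layers, and the background return is constant across the scene. None of
the canopy's structural detail (leaf angle, panicle inclination, row
geometry) enters.

### Scale handling

The physical derivation lives in linear power, but practitioners routinely
fit the saturating form directly to σ⁰ in dB, and the bundled fitted
parameters are dB-scale. Every parameter object (`WCMParams`,
`InversionCoeffs`, `BackscatterRaster`, `WCMCurveFit`) therefore carries an
explicit scale tag; operations that are only meaningful on one scale
(speckle filtering, the full soil-background model) raise
`ScaleMismatchError` on the wrong one. Incidence angles are degrees
everywhere and converted with `cos(radians(θ))`; θ defaults to 50°.

### Inversion edge cases

`sigma0 ≥ C` has no pre-image and raises `SaturationError`. A retrieval
below zero water (observation darker than the fitted range) is returned
unclipped with an `InversionRangeWarning`: near-saturation scatter is
expected in field data and silent clipping would bias parcel means. In the
parcel pipeline, saturated units are dropped from the mean, counted, and a
`SaturationWarning` is issued past 50%.

## Curve fitting

`fit_wcm_curve` fits `sigma0 = C − exp(−(x − a)/b)` by trust-region
reflective least squares (`scipy.optimize.least_squares`) with the analytic
Jacobian. Start values: `C = max(σ⁰) + 1 dB`, `b = range(x)/2`, `a` solved
exactly from the median point. Bounds are physical: `C` within
`(max(σ⁰), max(σ⁰) + 30 dB]` (the asymptote must clear every observation
for the log inversion to exist, and cannot sit arbitrarily far above the
data), `b ∈ (0, 10] kg/m²` (from `b = cosθ/2D` with any plausible crop
attenuation `D ≳ 0.05 m²/kg`), `a` within ±50 kg/m² of the survey span.
Tolerances are 1e−12 (1e−10 on the gradient) with a 400-evaluation budget
and up to 5 jittered restarts; an iteration-budget exit is accepted as a
solution when no restart improves on it, because in the saturated regime
(below) the cost surface has a genuinely flat valley and demanding a
first-order optimum there is meaningless. R² is the pseudo-R²
`1 − SS_res/SS_tot`; RMSE is over residuals.

### Identifiability in the saturated regime

The bundled fitted curves place the bend of the exponential at
`x ≈ a < 0` — negative panicle water. Over any physical survey range
(0.3–0.8 kg/m² mature, 0.5–1.7 kg/m² grouting) the exponential term is a
0.03–0.06 dB correction on a constant. Consequences, measured by
simulation in this package's test suite:

* with dB noise at or above ~0.01, `(C, a, b)` are jointly unidentifiable
  — estimates scatter across the allowed box and the constraint
  `C > max(σ⁰)` truncates the error distribution asymmetrically, so the
  fitted `C` is biased high by construction (the true `C` lies within
  noise of the brightest observations);
* in the near-noise-free regime the fit is consistent: mean parameter
  error falls ~0.37 → 0.035 → 0.0035 as σ_dB drops 1e−3 → 1e−4 → 1e−5,
  and noise-free data returns the generating parameters to < 1e−4
  relative;
* the per-plot water retrieval inherits the flatness: 0.05 dB of σ⁰ noise
  maps to order-1 kg/m² retrieval error. Parcel-level yield still averages
  much of this out, but single-plot retrievals in this regime should not
  be over-interpreted.

The linear calibrations are unaffected (ordinary OLS on a well-spread
regressor) and are the strongly identified part of the chain.

## Yield arithmetic

Unit plumbing follows Chinese agronomic convention: 1 mu = 666.667 m²,
1 hm² = 15 mu. Ear wet weight (kg/m²) × 666.667 gives wet yield kg/mu; a
moisture retention factor converts to dried grain — defaults 0.69 for
fully mature and 0.72 for grouting-stage rice, inferred from the bundled
verification pairs and explicitly site-specific. The grain model uses
`grains/m² × filled_fraction × TGW/1000` g/m², with the filled fraction
taken from the survey's filled/total grains per ear when available.
Accuracy metrics: `AE = |est − meas|`, `RE = 100·AE/meas`,
`P = 100 − RE`; reports are rounded half-up to 2 decimals for display
while internal arithmetic stays unrounded. The survey table's printed
kg/mu column is not trusted blindly: `check_unit_consistency` flags rows
whose kg/mu disagrees with kg/hm²/15 (two of the bundled grouting-stage
rows differ by exactly 20 kg/mu, cause unknown), and derived quantities
are recomputed from kg/hm².

## Raster handling

Rasters are plain 2-D arrays on a north-up affine grid (top-left origin,
square pixels, pixel-centre convention, row-major 0-based indexing); file
I/O is the ESRI ASCII grid text format plus CSV/GeoJSON point footprints.
Window averaging for a plot selects the `ceil(side/pixel)`² block (5×5 for
1.5 m plots at 0.3 m) centred on the pixel containing the footprint
centre — no sub-pixel interpolation — and averages in linear power, the
physically correct domain; the dB-domain mean is reported alongside for
sensitivity (by Jensen's inequality it can only be lower). Speckle
filtering requires linear power. The Lee filter uses local mean/variance
from a moving window with noise variation `Cu² = 1/ENL`, weight
`k = max(0, (var − Cu²·mean²)/(1 + Cu²))/var`; the boxcar is a plain
moving average. Default order is filter → extract; both orders are
possible since the operations are independent.

## Synthetic data

The generator reproduces the assumed statistical structure, per parcel
preset ("mature": 28 plots, water 0.3–0.8 kg/m²; "grouting": 30 plots,
0.5–1.7 kg/m²), with truth parameters equal to the bundled fitted models:

* `w1h1 ~ Uniform(range)`; `w2h2 = p·w1h1 + q` + truncated Gaussian
  (σ = 0.3 kg/m², consistent with the moderate scatter of the layer
  relation);
* `σ⁰ = C − exp(−(w1h1 − a)/b)` + Gaussian in dB (σ = 0.05 dB default —
  deliberately optimistic radiometry; see identifiability above: the
  curve-fit R² only reaches the bundled fits' 0.47–0.62 range for
  σ_dB ~ 0.005–0.01);
* ear wet weight and grain density as the linear calibrations + truncated
  Gaussian (0.05 kg/m² and 3000 grains/m²: the noise implied by
  calibration R² in the 0.84–0.94 range);
* rasters: each pixel takes the linear power of its nearest plot (so a
  footprint window is internally homogeneous), then unit-mean gamma
  speckle with shape ENL (default 4) multiplies in linear power;
  `ENL = inf` disables speckle;
* field truth aggregates the plot grain densities so that the record's
  kg/hm² equals the grain-to-mass arithmetic exactly (noise-free closure
  of the whole pipeline is then exact by construction, which is what the
  closure test asserts).

Everything is deterministic given the config seed (the raster stream is
offset by +1 so plot and speckle noise are independent).

What the generator does **not** emulate: spatial correlation of speckle
and of canopy water, mixed rice varieties within a parcel, phenological
drift between acquisition and harvest, bird damage and other harvest
losses, and the original survey's unexplained sample attrition. Passing
tests therefore demonstrate correctness of the estimation machinery under
the stated noise model, not field-readiness of the radiometric
assumptions.

## Problem sizes

Defaults keep every check cheap: surveys of 28–40 plots (500 for speckle
statistics), 200-seed Monte-Carlo for bias/RMSE ladders, 1000-point
parameter grids for the inversion round trip, and 200×200-pixel rasters —
sizes at which the Monte-Carlo error bars are already far tighter than
the effects being measured.
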