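# Methods

This note documents the science implemented in `traitgpr`: the models, the
parameters that matter, the synthetic world the package ships, and the
numerical choices behind the defaults.

## 1. The retrieval problem

Optical satellite imagers measure top-of-atmosphere (TOA) radiance; ecology
wants surface vegetation traits.  `traitgpr` implements a *hybrid* retrieval:
a physical forward model generates pairs (state → radiance) over a designed
range of canopy and atmosphere conditions, and a machine-learning regressor
is trained on those pairs to run the mapping backwards, per pixel, with a
per-pixel uncertainty.  Four traits are retrieved:

| trait | meaning | units | label definition in the simulator |
|-------|---------|-------|-----------------------------------|
| LCC   | leaf chlorophyll a+b content | µg/cm² | state variable, copied |
| LAI   | leaf area index | m²/m² | state variable, copied |
| FAPAR | fraction of absorbed PAR (400–700 nm), instantaneous | – | (1 − e^(−k(θs)·LAI)) · ā_PAR |
| FVC   | fractional vegetation cover | – | 1 − e^(−k·LAI), k = 0.5 |

FVC comes from the nadir gap fraction P = exp(−k·LAI) (Beer–Lambert).  The
extinction coefficient k is not uniquely defined by theory for all canopies;
the package defaults to k = 0.5, the spherical leaf-angle value at nadir,
and exposes it everywhere it is used.

## 2. The forward simulator (stand-in)

Operational hybrid pipelines couple a full canopy radiative-transfer model
(SCOPE-class) to a full atmospheric code (6SV-class).  Those are heavyweight
external tools; `traitgpr` replaces them with closed-form stand-ins chosen
so that every limit is testable exactly:

* **Leaf**: absorptance a(λ) = 1 − exp(−[LCC·k_cab + Cxc·k_car + Cw·k_w +
  Cdm·k_dm]/N), with Gaussian specific-absorption shapes (chlorophyll peaks
  at 450 and 670 nm, carotenoids at 500 nm, water at 940 nm, dry matter
  spectrally flat).  N is the mesophyll structure parameter.
* **Canopy**: single-scattering albedo ω = 1 − a; infinite-canopy
  reflectance ρ∞ = (1 − √(1−ω))/(1 + √(1−ω)); directional extinction
  k(θs) = (0.5 + 0.2·LIDF)/cos θs; canopy reflectance relaxes from the soil
  background to ρ∞ as ρ_c = ρ_s·e^(−2k(θs)·LAI) + ρ∞·(1 − e^(−2k(θs)·LAI)).
* **Soil**: a brightness-scaled linear soil line darkened by moisture,
  ρ_s = B·(c₀ + c₁(λ−400))·(1 − 0.5·SMC/55).
* **Atmosphere**: Rayleigh τ_R ∝ λ⁻⁴; aerosol τ_A = AOT₅₅₀·(λ/550)^(−α)
  (Ångström law); Gaussian ozone (Chappuis-like, 600 nm) and water-vapour
  (940 nm) bands scaled by O₃ and CWV; single-scattering path reflectance
  with the Rayleigh phase function and a Henyey–Greenstein aerosol phase;
  spherical albedo S = clip(0.92·τ_R + (1−g)·τ_A, 0, 0.5).
* **Coupling** (Lambertian): L(λ) = (E0·cosθs/π)·(ρ_path +
  T_dn·T_up·ρ_c/(1 − S·ρ_c)), with E0 a smooth Planck-shaped solar
  irradiance.  Radiance units are W m⁻² sr⁻¹ µm⁻¹.
* **Bands**: spectra are simulated at 1 nm from 400–1020 nm and convolved
  with 21 Gaussian relative spectral responses at the OLCI band centers and
  widths.

All spectral constants live in `forward.CONSTANTS` under a version tag; the
chain is bitwise deterministic given (state, constants version).

**What the stand-in does not emulate.** Multiple scattering between canopy
layers, the red-edge structural detail, hot-spot/BRDF effects, O₂
absorption in the narrow 761–768 nm bands, Fraunhofer lines, gaseous
absorption fine structure.  The consequence that matters (Section 6): the
21-band spectrum carries *less* information about LAI and FVC than a full
RTM produces, so retrieval accuracy bounds measured in this world are not
directly comparable to full-RTM figures.

## 3. Sampling design and training pool

States are drawn from a declarative design (uniform for predicted traits
and geometry, truncated Gaussian for naturally clustered variables,
constants where fixed).  Ranges: LCC ∈ [0, 95.6] µg/cm², LAI ∈ [0, 7],
SZA ∈ [20°, 40°], OZA ∈ [−10°, 10°], RAA = 180°, AOT₅₅₀ ∈ [0.05, 0.5],
CWV ∈ [0.4, 4.5] g·cm⁻², O₃ ∈ [0.25, 0.35] atm-cm, among others.
Truncated Gaussians are drawn by rejection (no probability atoms at the
bounds); note the truncated mean shifts away from the nominal mean when the
bounds are asymmetric — tests check against the exact truncated-normal
moments.

The default pool is 1000 directly simulated samples plus 1000 synthetic
"mixed-scene" samples: convex vegetated/bare-soil mixtures
f·L_veg + (1−f)·L_soil with f ~ U(0,1) and labels mixed with the same f
(the area-fraction reading of a heterogeneous 300 m pixel).  This stands in
for spectra extracted from real acquisitions, whose labels in an
operational pipeline come from external products; the mixture labels are a
declared substitute, not that procedure.  Pool total: 2000.  One random
250-sample subset (shared across traits) trains the models; the 1750
leftovers validate them.  The 250 cap mirrors the memory ceiling of
cloud-platform deployment and the O(N³) cost of exact GPs.

## 4. The Gaussian-process engine

Exact GP regression with the anisotropic (ARD) squared-exponential kernel

    k(x_i, x_j) = σ_s² · exp(−½ Σ_b [(x_i,b − x_j,b)/σ_b]²)

Hyperparameters θ = {σ_s², σ_1..σ_D, σ_n²} are found by maximizing the log
marginal likelihood over log-parameters with analytic gradients (L-BFGS-B,
box −20..20 in log space, 5 seeded restarts; initial length scales from
per-dimension spread, σ_s² = var(y), σ_n² = 0.01·var(y)).  Inputs are
standardized per band and the output mean subtracted before training; both
are stored on the model and inverted at prediction, so they affect
optimizer conditioning only.

Prediction uses the Cholesky factorization L·Lᵀ = K + σ_n²I and the weight
vector α = Lᵀ\(L\y): mean f(x*) = k_*ᵀα, variance σ_f²(x*) = k(x*,x*) −
vᵀv with v = L\k_*.  All pixel-independent terms (L, α, normalization) are
precomputed once per model and serialized, so a pixel costs two triangular
solves — the same factorization a cloud deployment would precompute.  A
brute-force inversion path (`predict_direct`) exists purely as a test
oracle.

**Variance convention.** Definitions in the literature differ on whether
the noise variance is added to the prior self-covariance: the package
implements both (`sigma_variant="latent"` default, `"observation"` adds
σ_n²) rather than guessing which one a given deployment used.

**Numerical choices.** If the Cholesky fails, jitter starts at
1e−10·mean(diag K) and escalates ×10 to 1e−4 before raising.  Predictive
variances are clipped at 0 against rounding.  Training warns above
N = 2000 (cubic cost).

## 5. Mapping, compositing, gap-filling

* **Masking**: pixels with the bright (cloud-suspect) or inland-water
  flag bit set are invalid; bit positions are configurable (synthetic
  scenes use bit 0 = bright, bit 1 = water).  Invalid pixels are NaN
  internally and never influence any downstream statistic.
* **CV maps**: relative uncertainty CV = 100·σ/mean is undefined near
  zero; the default cut is mean > ε with ε = 1% of the model's training
  output range.
* **Compositing**: the default predicts once on the per-pixel mean
  radiance x̄ over the window (one GP evaluation per pixel per month);
  the alternative averages per-scene predictions, combining σ as the RMS
  over dates (no standard combination rule exists; RMS is the package's
  choice).  The two differ only through the GP's nonlinearity — with a
  linear predictor they agree exactly, which the tests use as an isolating
  property — and `composite_deviation` measures the difference on sampled
  pixels.
* **Gap-filling**: the same ARD-SE GP run in one dimension (time,
  fractional days) with *fixed* hyperparameters {length scale, variance,
  noise} — no per-series optimization, which is what makes large-scale
  processing affordable.  Pooled values come from per-series
  marginal-likelihood optima aggregated by the median of logs.  When no
  fitted values are available the defaults are length scale 60 days,
  variance (trait range/4)², noise 5% of variance — declared substitutes
  chosen as plausible seasonal-vegetation scales, not fitted constants.
  The σ series is interpolated with the same mechanics and clipped at 0.
* **Monthly chunking**: long records are filled in monthly windows using
  observations within `overlap_scales` length scales (default 3) of the
  window, all chunks sharing the whole-series output offset.  Measured
  accuracy against the whole-series posterior (the oracle): ~4e−3 trait
  units max at 3 length scales with near-daily sampling, <1e−3 at 5, ~1e−5
  at 12.  Exact SE-kernel posteriors have long-range weights when
  σ_n²/σ_s² is small, so truncation error decays more slowly than the
  kernel itself — raise `overlap_scales` when seamlessness matters more
  than memory.

## 6. Validation statistics and measured accuracy

Goodness of fit: R² = 1 − SS_res/SS_tot, RMSE, and NRMSE = 100·RMSE/range
of the validation references (denominator configurable to the mean; range
is the default and is reported in the output metadata).  Series
comparison: ΔX% = 100·|X̄_est − X̄_ref|/X̄_est — the retrieved series'
mean in the denominator, the convention that reproduces the published
worked examples (0.85 vs 0.91 → 6.59%; 0.51 vs 0.55 → 7.27%).  Difference
maps are signed, 100·(est − ref)/est, with the same denominator
convention; block-mean regridding marks a target cell invalid when fewer
than 50% of its contributors are valid (configurable).

On the seeded default synthetic pipeline (the numbers the acceptance
script recomputes):

* the trait ordering matches expectation — FAPAR is retrieved best and LAI
  worst (saturation of the radiance signal above LAI ≈ 3–4);
* LAI NRMSE lands near 20% and FVC near 15%.  The FVC figure is the
  stand-in's information ceiling, not an optimizer artifact: an
  independent GP implementation (scikit-learn, ARD RBF + white noise)
  scores within 0.3 percentage points on the identical split, and
  quadrupling the training set improves FVC only to ~12.6%.  Because
  FVC = 1 − e^(−0.5·LAI) while the radiance attenuates as
  e^(−2k(θs)·LAI), FVC inherits the LAI saturation exactly where the
  closed-form spectrum has stopped changing; a full RTM retains more
  sensitivity there.  Bounds quoted from full-RTM studies (e.g. FVC NRMSE
  ≈ 6.7%) are therefore not reproduced in this world, and the acceptance
  suite reports that honestly rather than retuning the simulator;
* gap-filling with pooled global hyperparameters degrades withheld-date
  reconstruction RMSE by ~2–5% (ensemble mean) relative to per-series
  optimization, comfortably inside the ≤7% operating assumption.

A green test in this package establishes correctness of the algorithms and
their numerics on the synthetic world; it does not establish accuracy on
real satellite acquisitions, which differ in spectral richness, label
noise, atmospheric correction residuals and land-cover heterogeneity.

## 7. Tunable parameters that matter

| parameter | default | where | why |
|-----------|---------|-------|-----|
| k (FVC extinction) | 0.5 | `forward.CONSTANTS` | spherical leaf angle, nadir |
| grid step | 1 nm | `spectral.spectral_grid` | resolves the narrowest (2.5 nm) band |
| pool sizes | 1000 + 1000 | `pools.build_training_pool` | simulated + mixed-scene recipe |
| n_train | 250 | `models.split_pool` | deployment memory ceiling, O(N³) training |
| n_restarts | 5 | `ARDGaussianProcessRegressor` | multimodal marginal likelihood |
| sigma_variant | latent | `ARDGaussianProcessRegressor` | Eq-7-style latent variance |
| composite mode | mean_radiance | `mapping.composite_predict` | one GP pass per window; stable means |
| CV ε | 1% of training range | `mapping.predict_scene` | relative error undefined near 0 |
| global hp | 60 d, (range/4)², 5% | `timeseries.default_global_hyperparams` | declared substitutes |
| overlap_scales | 3 | `timeseries.chunked_gapfill` | memory/accuracy trade-off (see §5) |
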