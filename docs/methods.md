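# Methods

`leafgas` analyses leaf gas-exchange experiments that probe how growth at
elevated CO2 changes photosynthetic capacity and stomatal control: A/Ci
response curves, stepped external-CO2 (Ca) sessions, and lights-off closure
traces, reduced to per-species relative changes (Δ) and the regressions
linking them. This note records the models, the operational definitions, the
estimator design, and what the synthetic data generator does and does not
emulate.

## Photosynthesis model

Net assimilation follows the Farquhar–von Caemmerer–Berry (FvCB) model for
C3 leaves: the minimum of a Rubisco-limited and an RuBP-regeneration-limited
rate, each a saturating function of chloroplast CO2 (`Cc`), minus day
respiration `Rd`:

    Ac = Vcmax (Cc − Γ*) / (Cc + Kc(1 + O/Ko))
    Aj = (J/4) (Cc − Γ*) / (Cc + 2Γ*)
    A  = min(Ac, Aj) − Rd

With a finite mesophyll conductance `gm`, `Cc = Ci − A/gm`, and each branch
becomes a quadratic in `A` whose smaller root is the physical solution (the
other root diverges as `gm → ∞`; we also prove, and property-test, that the
smaller root always keeps `Cc > 0` for admissible parameters). All CO2
quantities are mole fractions (μmol mol⁻¹ ≡ ppm), not partial pressures;
callers who work in pressure units convert at the boundary.

Assumptions and fixed choices:

- Single operating temperature of 25 °C (the standard cuvette temperature);
  no temperature-response functions. Kinetic constants default to
  Bernacchi-style 25 °C values — `Kc = 404.9 μmol mol⁻¹`,
  `Ko = 278.4 mmol mol⁻¹`, `Γ* = 42.75 μmol mol⁻¹`, `O = 210 mmol mol⁻¹` —
  all exposed in `KineticConstants`.
- Measurements are taken at saturating light (2000 μmol m⁻² s⁻¹ PAR), so the
  operating electron transport rate `J` is identified with `Jmax`; no light
  response is modelled.
- The Rubisco/RuBP transition is the pointwise branch minimum; no smoothing
  hyperbola and no TPU limitation.
- Stomatal conductance to water vapor (mmol m⁻² s⁻¹) converts to a CO2 basis
  (mol m⁻² s⁻¹) through the 1.6 diffusivity ratio; total conductance to CO2
  is the series combination `Gs·Gm/(Gs+Gm)`, which lies in
  `[min(Gs,Gm)/2, min(Gs,Gm)]`.

## A/Ci estimator

`fit_aci` estimates `(Vcmax, Jmax, Rd, gm)` by bounded nonlinear least
squares against observed `(Ci, A)` pairs, with default bounds
`Vcmax ∈ [1, 400]`, `Jmax ∈ [1, 600]`, `Rd ∈ [0, 5]` (optionally fixed via
config) and `gm ∈ [0.01, 10] mol m⁻² s⁻¹`. Three design points matter:

1. **Branch-transition enumeration.** The min-rule objective is non-smooth
   where the limiting process switches, and trust-region descent reliably
   stalls in branch-assignment local minima. The fit therefore enumerates
   candidate Rubisco→RuBP transition positions along the Ci-sorted curve,
   solves each smooth forced-assignment subproblem (analytic Jacobians by
   implicit differentiation through the quadratic: `dA/dθ = −F_θ/√disc`),
   and polishes the best candidates under the free min rule. On noiseless
   forward data this recovers the generating parameters to optimizer
   precision (≲1e-12 relative).
2. **Boundary model selection.** A solution pinned at the `gm` upper bound
   is the rectangular (`gm = ∞`) model straining against its cap; the fit
   then refits with `gm` genuinely infinite and keeps that model when it
   fits at least as well, reporting `gm_effectively_infinite`.
3. **Identifiability.** A single 16-point curve identifies `gm` only jointly
   with `Vcmax` (a long, banana-shaped likelihood ridge). Linearized
   standard errors are reported from the residual Jacobian, and a fit is
   flagged unreliable when it did not converge, `gm` sits on a bound, or the
   `Vcmax` relative SE exceeds 50%. For low-signal curves the likelihood
   along the ridge can even be bimodal — a wrong mode with much smaller `gm`
   and much larger `Vcmax` fits almost equally well and *looks* sharply
   determined, so SE-based screening cannot catch it.

Because of point 3, the study-level pipeline (`analyze_study`) uses a
two-pass scheme: after per-leaf fits, the log-`gm` values of reliable fits
define a consensus (median, MAD-based sigma with a 0.25 floor), and each
leaf is refitted with a weak lognormal penalty on `gm` scaled by that leaf's
own residual noise (empirical-Bayes shrinkage). Well-identified curves move
negligibly; bimodal ones snap to the mode consistent with the rest of the
study. Unreliable fits contribute `NaN` to treatment means rather than
distorting them. Single-curve calls to `fit_aci` are unaffected.

`P_N max` is the fitted model's assimilation at the 2000-ppm end of the
protocol (the largest applied Ca).

## Closure kinetics

A lights-off trace is summarised by: the pre-dark baseline `gs0` (mean of
the final 60 s before lights-off; a coefficient of variation above 2% flags
an unstable baseline), the dark minimum `gs_min`, the amplitude
`gs0 − gs_min`, the half-closure time `t50`, the time to maximum closure
`t_max`, the two mean closure speeds `speed50 = 0.5·amplitude/t50` and
`speed_max = amplitude/t_max`, and the percentage of `gs0` remaining after
exactly 1 h of darkness.

Operational definitions (all config-exposed):

- The first 120 s after lights-off are excluded from detection: real cuvette
  traces show a transient there that reflects the chamber's
  humidity/temperature control, not the stomata.
- The trace is smoothed with a 5-sample (≈50 s) centered moving median
  before crossing detection — robust to single-sample spikes and exactly
  transparent on monotone traces.
- Crossing times are refined by linear interpolation between the bracketing
  samples, so the 10-s cadence does not quantize speeds.
- "Maximum closure" is the first entry into a band 2% of the amplitude above
  `gs_min`, held for ≥3 consecutive samples.
- An amplitude below 5 mmol m⁻² s⁻¹ is flagged "no-closure"; speeds are then
  undefined and the 1-h percentage is still reported.
- The 1-h metric is canonical as percent *remaining* (`100·gs/gs0`); the
  complementary percent *closed* (`100 − that`) is emitted alongside, and it
  is the "closure to darkness" parameter entering the Δ analysis, so that
  tighter closure means a larger value.

On noiseless exponential decay these definitions land `t50` within one
sampling interval of `τ ln 2` and `t_max` within one interval of `τ ln 50`,
and `speed50 ≥ speed_max` for any monotone decay.

## Ca step response

The stepped protocol records plateau Gs at 200, 400, 750, 1000 and 2000 ppm
plus a separate 50-ppm reading that induces full opening and is promoted to
`Gs_max`. Stomatal closure to CO2 is `100·gs(2000)/gs(400)` (percent
remaining; 100 = the insensitive phenotype). When raw traces are supplied,
the plateau is the mean of the final 60 s of the stable phase; recorded
single values pass through unchanged.

## Synthetic data generator

The generator produces instrument-style datasets with known truth so every
stage is verifiable by parameter recovery:

- **Steady-state coupling.** For each applied Ca the leaf model couples FvCB
  assimilation to a Ball–Berry stomatal model
  `gs = g0 + g1·A·rh/Ca` (floored at `g0`), solved by bisection on the
  diffusion budget `Ci = Ca − A/gs_CO2` to 1e-6 ppm. Ball–Berry was chosen
  over Medlyn because it needs only the relative humidity and Ca already in
  the protocol; defaults `g1 = 9`, `g0 = 20 mmol m⁻² s⁻¹`, `rh = 0.5`.
- **Dark closure** is first-order exponential relaxation from the coupled
  400-ppm baseline to a dark floor, the simplest model consistent with
  observed closure traces, with an optional half-sine artifact bump (default
  90 s, 30 mmol m⁻² s⁻¹) in the first seconds of darkness and Gaussian
  sensor noise.
- **The 50-ppm opening reading** cannot come from Ball–Berry (assimilation
  collapses at 50 ppm, which would close the modelled stomata, whereas real
  stomata open fully), so it is modelled directly as an opening factor
  (default 1.2) times the largest noiseless step plateau.
- **Fluorescence** values are constructed to satisfy the scenario's target
  Fv/Fm and ΦPSII exactly.
- **The default study** is five crops (oat, wheat, cotton, sunflower,
  barley) × two growth CO2 levels × four replicates. Ambient capacities and
  the elevated:ambient capacity ratios are set at the scale reported for
  these species (the dicots lose roughly half their Vcmax at 2000 ppm; the
  grasses retain most of theirs), and closure impairment is *coupled* to the
  capacity loss: the dark-floor fraction rises, and the closure time
  constant lengthens, in proportion to the Vcmax reduction. Replicates get
  lognormal leaf-to-leaf variation (CV 7%) on Vcmax, Jmax, τ and the dark
  floor, and per-replicate seeds derived by SHA-256 from (master seed,
  species, treatment, replicate), so a fixed master seed reproduces the file
  tree byte-identically.
- **The null design** makes the elevated scenario identical to the ambient
  one and switches replicate jitter off, so the CO2 contrast is pure
  Gaussian measurement noise — the exact sampling model under which the
  ANOVA treatment test's p-value should be uniform.

What the generator does *not* emulate: leaf energy balance and transpiration
feedback on VPD, chamber CO2/humidity control loops, instrument drift or
autocorrelated noise, stomatal reopening/oscillations and circadian gating,
Ci inference error (real analyzers compute Ci from fluxes; the generator
records the solver's Ci), and any temperature variation. Passing recovery
tests therefore demonstrate that the estimators are correct and
well-calibrated under the stated sampling models, not that they are robust
to every instrument pathology of real traces.

## Statistics

- **Δ (relative change)** is the elevated-CO2 value as a percentage of the
  ambient value, computed per species on treatment means (growth chambers
  preclude replicate pairing), with a seeded nonparametric bootstrap over
  replicates (1000 resamples) for its standard error.
- **Regressions** are ordinary least squares; the F statistic satisfies
  `F = R²/(1−R²)·(n−2)` with `df = (1, n−2)` exactly, and p-values come from
  that F distribution. The headline Δ-vs-Δ regressions run at the species
  level (n = 5 points).
- **One-way ANOVA** is the classical between/within decomposition (via
  `scipy.stats.f_oneway`); **two-way ANOVA** is the additive
  (no-interaction) model with error df `N − a − b + 1`, implemented directly
  for balanced designs and cross-checked against `statsmodels.anova_lm` in
  the tests. Unbalanced designs are rejected. No multiple-testing
  correction is applied; p-values are reported at full precision.
- **Fluorescence indices**: `Fv/Fm = (Fm − Fo)/Fm` and
  `ΦPSII = (Fm′ − Fs)/Fm′`, both constrained to (0, 1) by input contracts.

## Verification experiments and problem sizes

The evaluation module re-runs, from scratch: the published-table Δ
arithmetic for wheat and sunflower Gs; solver-vs-oracle agreement on a
1000-point (Ci, gm) grid, with the oracle a damped fixed-point iteration on
`Cc` whose damping factor `gm/(gm + max A′)` guarantees contraction; a
100-curve Monte-Carlo recovery study at noise sd 0.5 μmol m⁻² s⁻¹ on the
16-step protocol grid; closed-form kinetics checks at τ ∈ {100, 300, 600} s;
OLS/ANOVA oracle identities plus a 200-seed null-design calibration of the
two-way CO2 test; and the 100-study end-to-end direction check of the
Δ-Vcmax vs Δ-closure-to-darkness regression. These sizes make every
experiment individually reproducible in minutes on one core.

On the recovery study: with truth `(100, 150, 1.5, 0.3)`, 16 points and
noise sd 0.5, the Vcmax/gm ridge puts the global least-squares estimator's
median |relative error| for Vcmax near 5% — the linearized
information bound is about 4%, and ridge curvature inflates the realized
spread — so the 5% recovery check sits at the estimator's intrinsic
precision limit and its outcome varies slightly with the seed. Jmax (≈1%)
and the factor-1.5 gm check (≈80%) have more headroom.

## Known limitations

- gm is treated as constant along each curve (the estimator's premise); if
  gm varies with Ci the estimate is an effective average.
- The additive two-way ANOVA cannot detect species×CO2 interactions by
  construction.
- Δ ratios of means have no exact small-sample distribution; the bootstrap
  SE is descriptive.
- The kinetics definitions assume an eventually monotone approach to a
  plateau; oscillating traces will yield early `t_max` detections within the
  tolerance band.
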