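# Methods

This note records the models the package implements, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
test battery does and does not establish.

## Scene model

**Working grid.** All spectra live on a fixed 400–700 nm grid with 10 nm
spacing (31 samples). CIE quantities are computed by rectangle-rule
summation against the standard abridged 10 nm tabulations of the CIE 1931
2° colour-matching functions and the D65 spectrum, which ship as package
data. On this truncated grid the normalized D65 chromaticity evaluates to
(0.313, 0.329) at three decimals, matching the conventional values, so no
finer grid is needed for the analysis. Cone spectral sensitivities are
derived from the colour-matching functions by the Hunt–Pointer–Estévez
transformation (von Kries normalization, tiny negative lobes clipped to
zero); the cone stage here is deliberately simplified — it feeds a linear
observer, for which any fixed positive spectral weighting is equivalent up
to calibration.

**Background reflectance.** Surface reflectance is modelled as a mean
spectrum plus a six-dimensional principal-component expansion whose weight
covariance is estimated from an ensemble; samples are drawn from a
mean-zero multivariate normal with covariance σ²·C, where the covariance
scalar σ² interpolates between a frozen background (σ² = 0) and
ensemble-level variability (σ² = 1). Draws with any value outside [0, 1]
are rejected and redrawn (budget 10,000 per sample; exhausting it is an
error, never a clip — rejection, not clipping, is the model). Achromatic
variants replace an *accepted* sample with the flat spectrum at its
wavelength mean, in that order, so achromatic samples inherit the
realizable chromatic distribution of overall lightness. Rejection
truncates the sampling distribution, so at σ² = 1 the empirical weight
covariance sits somewhat below σ²·C; tests check trace agreement loosely
(ratio in (0.7, 1.05]) rather than element-wise equality.

**Illumination.** One illuminant per scene, shared by all light sources: a
fixed relative shape (D65 divided by its wavelength-mean power) times an
intensity scale exp(U), U uniform on [ln(1−δ), ln(1+δ)]. The range
parameter δ < 1 keeps the interval positive. The log-uniform reading of
"uniform on the interval" follows the distribution whose logarithm is
uniform on the log-endpoints.

**Stimuli.** The rendered 3D scenes of the original experiments are
replaced by a patch mosaic (default 5×5, centre patch = target). A linear
receptive field's response depends on the image only through RᵀI, and a
spatially uniform patch responds as a unit, so the mosaic preserves the
observer mathematics exactly while making scene generation a handful of
vector operations. The target patch carries a spectrally flat reflectance
at the requested value, which makes its luminous reflectance factor exact
by the flat-spectrum identity. Condition grids ship as defaults:
σ² ∈ {0, 0.01, 0.03, 0.1, 0.3, 1.0} (chromatic), {0.03, 0.3, 1.0}
(achromatic), δ ∈ {0, 0.05, …, 0.30}; comparison LRF levels are the 11
equally spaced values on [0.35, 0.45] with standard 0.40.

**Cone responses.** Expected counts are gain × integration time (default
100 ms) × the spectral inner product of patch radiance with each cone
fundamental, optionally Poisson-perturbed, then divided by each class's
integrated sensitivity so a flat spectrum drives the three classes
equally. The default threshold pipeline runs with Poisson noise off:
the observer's intrinsic noise is modelled as a single additive Gaussian
at the response level, which subsumes photon noise for this analysis.
Optics, cone-mosaic sampling, and demosaicing are not emulated.

## Observer and threshold convention

The LINRF observer applies a centre-surround weight grid (+1 on target,
v_s ≤ 0 elsewhere, identical across L, M, S), sums, adds mean-zero
Gaussian intrinsic noise of sd σᵢ, and chooses the interval with the
larger response (exact ties — possible only at σᵢ = 0 — are broken by a
fair coin). Standard and comparison intervals never share scene draws.

**Calibration.** The receptive field carries a calibration scale set so
that the least-squares slope of mean noise-free response against target
LRF equals 1 for the condition at hand; after calibration, responses and
σᵢ are in LRF units and directly comparable to thresholds. Calibration is
per condition because the mean intensity scale E[s] differs slightly from
1 under intensity variation (E[s] ≈ 0.969 at δ = 0.3); the slope is
independent of v_s and σᵢ, so the simulation fit calibrates once per
condition, not per grid point.

**Threshold.** Proportion-comparison-chosen data are fitted with the
lapse-adjusted cumulative normal (guess = lapse, λ ∈ [0, 0.05]) by
maximum likelihood over a fixed 3×3 deterministic multistart of
(PSE, log sd) with bounded L-BFGS-B refinement — fits are reproducible
without a seed. T is defined by inverting the *fitted lapse-adjusted*
curve at 0.76 and 0.50 (T = sd·Φ⁻¹((0.76−λ)/(1−2λ))); inverting the
lapse-free Φ instead is available as an option. With two independent
intervals of total response sd σ_η, the choice probability at offset ΔLRF
is Φ(ΔLRF/(√2σ_η)), so the fitted psychometric sd is √2σ_η and
T = √2σ_η·Φ⁻¹(0.76) = 0.9989·σ_η ≈ σ_η: the 0.76 criterion makes
threshold-squared an estimate of total response variance (d′ = 1), giving

    T² = σᵢ² + RᵀΣₑR,       RᵀΣₑR = σ²·RᵀΣₑ₀R.

The T² form is the dimensionally consistent one and is what the package
implements.

## Equivalent-noise fits

**Direct fit.** log T² = log(σᵢ² + level·σₑ₀²) by bounded least squares
on the log scale (both parameters ≥ 0), seeded from the curve endpoints.
Two exact points determine the parameters algebraically; a flat curve
collapses to pure intrinsic variance.

**Simulation fit.** Over a grid of (σᵢ², |v_s|), model thresholds are
simulated for every condition level and the mean squared error against
the measured thresholds is fitted with a full bivariate quadratic (six
coefficients, ordinary least squares); the analytic vertex — when the
Hessian is positive definite — gives the estimate, clamped to the grid
bounds, with fallback to the best raw grid point for indefinite surfaces
and a warning when the minimizer is pinned to a boundary. σₑ₀² is then
the quadratic form RᵀΣₑ₀R at the fitted surround: for background
variation, over fresh scenes at σ² = 1; for intensity variation, the
values RᵀΣₑ₀R(δ) at the positive δ levels are fitted with a·exp(bδ) and
evaluated at δ = 1 (δ = 0 is excluded — the exponential cannot pass
through zero). Extrapolating beyond the measured range amplifies
measurement noise roughly threefold, so the extrapolation test checks
the estimator's central tendency over replicates rather than single
draws. Default grids: σᵢ² log-spaced over three decades around the
no-variation T², |v_s| ∈ [0, 0.1] — the closed-loop recovery tolerance
is one grid cell, so grid resolution, not optimizer precision, limits
accuracy.

**Additivity.** For conditions {none, A, B, A+B}, ΔT² is each condition's
increase in mean squared threshold over the no-variation condition, and
the additivity gap is ΔT²(A+B) − ΔT²(A) − ΔT²(B). Under the model the two
sources are independent, but multiplicative intensity noise interacts
weakly with background variance (the product term var(s)·var(background)
contributes ~1–2% of the total), so the gap is near zero rather than
exactly zero; simulations show it well within twice the Monte-Carlo
spread of the gap estimate at 5,000 trials per level.

## Surrogate data

The surrogate reflectance ensemble draws 632 spectra (the size of the
combined natural ensembles the published reflectance statistics rest on)
from a Gaussian process: mean level 0.45, pointwise sd 0.12, squared-
exponential wavelength correlation with 80 nm length. These values were
chosen so that raw draws are almost surely realizable (>99% acceptance,
enforced), six components carry ≥99% of the variance (as for measured
ensembles), and scene luminances sit near the middle of the reflectance
range. The surrogate reproduces the *structural* assumptions of the
analysis — smoothness, low rank, physical realizability — and nothing
else: in particular it does not reproduce the chromaticity gamut of
natural surfaces, so passing tests certify the pipeline's statistics and
conventions, not any claim about real scenes or human observers.

Simulated trial tables use the same ψ as the fitting module with known
parameters; the default block is 30 trials at each of 11 levels (330
trials), matching the experimental block structure.

## Default observer parameters

The synthetic study conditions use intrinsic sd 0.02 LRF units and
surround sensitivity −0.05. These give a no-variation threshold of
≈0.020 — the level at which human observers pass the practice screen
(mean of the last two practice blocks ≤ 0.030) — and an equivalent noise
level σₑ₀²/σᵢ² of ≈1.3, inside the "within a factor of two of intrinsic"
regime that the human analysis reports. The published fitted values of
σᵢ² for human observers depend on the original rendered-image ensemble
and cone-mosaic scaling and are not reproducible at desk scale; the
package reproduces the *procedure* and validates it by closed-loop
recovery instead.

## Problem sizes

The test battery runs the simulations at reduced but statistically
adequate sizes, chosen once: psychometric simulations use 3,000–10,000
trials per level (the d′ = 1 convention check uses 100,000 trials);
closed-loop simulation fitting uses a 5×5 parameter grid at 600 trials
per level; additivity uses four replicates at 5,000 trials per level;
coverage of the threshold estimator uses 500 replicates at the
experimental 30 trials per level. The full suite completes in a few
minutes on one CPU.

## Known limitations

- The patch mosaic collapses all spatial structure; effects that depend
  on geometry, shadows, or the spatial extent of the surround are out of
  scope by construction.
- Rejection sampling truncates the reflectance distribution at high σ²;
  the model's "variance at σ² = 1" is the truncated ensemble's, which is
  the physically realizable quantity but not the nominal normal one.
- The additive-Gaussian reading of total response variability is an
  approximation under multiplicative intensity noise; the discrepancy is
  at the few-percent level at δ = 0.3 and is documented above.
- External per-observer trial tables and the measured reflectance
  ensembles can be analysed through the same CSV schemas, but no such
  data ship with the package.
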