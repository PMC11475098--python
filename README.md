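# equivnoise

Equivalent-noise analysis of human lightness discrimination.

## The problem

The light reaching the eye from an object confounds the object's own
surface reflectance with everything else in the scene: the reflectances of
the surrounding objects and the intensity of the illumination. A visual
system with good *lightness constancy* discounts those object-extrinsic
sources of variation. The equivalent-noise paradigm quantifies this: one
measures the threshold for discriminating two scenes by the lightness of a
target object while injecting controlled statistical variation into the
background reflectances (amount controlled by a covariance scalar σ²) and
the light-source intensity (amount controlled by a range parameter δ), and
asks how much extrinsic variance is needed before thresholds rise above
the observer's intrinsic floor.

This package implements that analysis end to end for a simulated
two-alternative forced-choice (2AFC) experiment:

- **statistical scene generators** — a PCA / multivariate-normal model of
  natural surface reflectance (covariance scaled by σ², samples rejected
  unless physically realizable, optional achromatic projection) and a
  normalized-D65 illuminant whose intensity is drawn log-uniformly on
  [1−δ, 1+δ];
- **a linear-receptive-field (LINRF) model observer** — a centre-surround
  field (centre weight +1 on the target, surround weight v_s ≤ 0) applied
  identically to the three cone-class images, plus additive Gaussian
  intrinsic noise; the observer picks the interval with the larger
  response;
- **psychometric fitting** — maximum-likelihood lapse-adjusted cumulative
  normal ψ(x) = λ + (1−2λ)Φ((x−PSE)/sd), with guess rate equal to lapse
  rate and λ ≤ 0.05; the threshold T is the LRF difference between
  ψ = 0.76 and ψ = 0.50, which corresponds to d′ = 1 in a two-interval
  task;
- **equivalent-noise fits** — the decomposition

      T² = σᵢ² + σ² · σₑ₀²

  fitted directly on the log-T² scale, or by closed-loop simulation of
  the LINRF observer over a grid of (σᵢ², v_s) with a quadratic-surface
  minimization; extrinsic variance computed as the quadratic form
  RᵀΣₑR over the image ensemble, with exponential extrapolation of the
  light-intensity variance to δ = 1; and the additivity decomposition
  comparing simultaneous variation against the sum of the individual
  variations.

Everything the pipeline consumes can be generated internally (a surrogate
low-rank reflectance ensemble and simulated trial tables), so the full
analysis runs without any external data. Target lightness is expressed as
the luminous reflectance factor (LRF): the luminance of a surface under
CIE D65 divided by the luminance of D65 itself.

## Worked example

```python
import dataclasses
import numpy as np
import equivnoise as en
from equivnoise.observer import ConditionSimulator
from equivnoise.stimulus import Condition, SceneModels

# 1. surrogate reflectance ensemble and PCA model
ensemble = en.make_surrogate_dataset(en.SurrogateDatasetSpec(seed=1))
model, frac = en.fit_reflectance_pca(ensemble, n_components=6)
print(f"six components explain {frac:.1%} of reflectance variance")
models = SceneModels(model)

# 2. calibrated LINRF observer, then thresholds across the sigma^2 grid
rng = np.random.default_rng(0)
thresholds, levels = [], [0.0, 0.01, 0.03, 0.1, 0.3, 1.0]
for s2 in levels:
    sim = ConditionSimulator(models, Condition(sigma2=s2))
    obs = en.LINRFObserver(en.ReceptiveField(sim.mask, -0.05), 0.0)
    obs = en.calibrate_rf_units(obs, sim, rng=rng)
    obs = dataclasses.replace(obs, intrinsic_sd=0.02)
    table = en.simulate_psychometric(obs, sim, n_per_level=3000, rng=rng)
    t = en.fit_psychometric(table).threshold
    thresholds.append(t)
    print(f"sigma^2 = {s2:<5} threshold T = {t:.4f}")

# 3. equivalent-noise decomposition of the threshold curve
fit = en.fit_noise_curve_direct(levels, np.array(thresholds) ** 2)
print(f"sigma_i^2 = {fit.sigma_i2:.2e}, sigma_e0^2 = {fit.sigma_e02:.2e}, "
      f"equivalent noise level = {fit.ratio:.2f}")
```

Output:

```
six components explain 100.0% of reflectance variance
sigma^2 = 0.0   threshold T = 0.0197
sigma^2 = 0.01  threshold T = 0.0200
sigma^2 = 0.03  threshold T = 0.0204
sigma^2 = 0.1   threshold T = 0.0210
sigma^2 = 0.3   threshold T = 0.0235
sigma^2 = 1.0   threshold T = 0.0304
sigma_i^2 = 3.92e-04, sigma_e0^2 = 5.31e-04, equivalent noise level = 1.35
```

Reading the numbers: with no background variation the simulated observer's
threshold (~0.020 LRF units) is set entirely by its intrinsic noise
(sd 0.02). Thresholds stay flat while extrinsic variance is small
compared with the intrinsic floor and rise once σ²·σₑ₀² becomes
comparable to σᵢ²; the two-parameter fit recovers the intrinsic variance
(3.9×10⁻⁴ ≈ 0.02²) and the extrinsic variance at natural-dataset
variability, whose ratio — the equivalent noise level — says the scene
variation affects the response about 1.35 times as strongly as the
observer's own noise.

## Command line

The `equivnoise` entry point wraps the library:
`sample-spectra`, `render`, `simulate`, `fit-psycho`, `fit-noise`,
`decompose`, and `replicate` (the full synthetic pipeline from one seed;
run twice with the same seed it produces byte-identical tables). Every
run writes a `run_log.json` with versions, the seed, and a config hash.

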