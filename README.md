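# robustbg

Robust background estimation for X-ray diffraction reflection shoeboxes.

When an integration program estimates the intensity of a Bragg reflection,
it first models the diffuse background under the peak from the surrounding
"background" pixels, then subtracts it from the summed foreground counts
(summation integration).  On modern photon-counting detectors the
background is often below one count per pixel, and the classical outlier
rejection schemes — σ-clipping, Tukey fences, trimming, normality-based
pruning — all assume approximately normal pixel values.  At Poisson means
near zero that assumption collapses: these filters systematically reject
the (rare) nonzero pixels, underestimate the background, inflate the
apparent intensities of weak reflections, and can even drive the background
estimate to exactly zero.

`robustbg` implements the alternative: a **robust generalized linear
model** of the background.  Counts are modelled as Poisson with a
log-linear mean (constant or planar),

```
log mu_i = x_i' beta ,        y_i ~ Poisson(mu_i) ,
```

and the coefficients solve the Huber-weighted quasi-likelihood score
equations

```
sum_i [ psi_c(r_i) - a_i(beta) ] (1 / sqrt(mu_i)) mu_i' x_i = 0 ,
```

where `r_i = (y_i - mu_i)/sqrt(mu_i)` is the Pearson residual,
`psi_c(r) = max(-c, min(c, r))` the Huber clamp, and
`a_i = E[psi_c(R_i)]` the Fisher-consistency correction (exact Poisson
expectation).  The default tuning constant `c ≈ 1.345` is derived by
root-finding the condition that the estimator attains 95% asymptotic
efficiency at the normal distribution; `c = inf` recovers the classical
Poisson GLM (whose constant-model MLE is the plain mean).  The equations
are solved by iteratively reweighted least squares and the coefficient
covariance is the sandwich `M^-1 Q M^-T` with exact Poisson moments of the
clamped residual.

The package also provides:

- the six traditional strategies (`null`, `truncated`, `nsigma`, `tukey`,
  `plane`, `normal`) for comparison (`robustbg.filters`);
- a synthetic shoebox simulator with known ground truth, hot pixels and
  zingers (`robustbg.simulate`);
- diagnostics: exact trimmed-Poisson-mean bias, index-of-dispersion
  selection, Poisson median-bound checks, zero-background fractions and a
  multi-method comparison driver (`robustbg.diagnostics`);
- a CLI (`robustbg simulate | fit | compare`) with JSON-lines shoebox files
  and byte-deterministic CSV outputs.

It is aimed at integration-pipeline developers and methods researchers who
want a reference implementation of the robust estimator and a controlled
test bed for outlier handling at photon-counting background levels.

## Worked example

A 9×9 shoebox with a true background of 5 counts/pixel and one 1000-count
hot pixel among the 72 background pixels:

```python
import numpy as np
from robustbg import (ShoeboxSpec, OutlierSpec, simulate_dataset,
                      constant_background_fit, run_comparison)

spec = ShoeboxSpec(background=5.0, outliers=OutlierSpec(n_hot=1, hot_value=1000))
sb = simulate_dataset(1, spec, seed=7)[0]
y = sb.background_values
fit = constant_background_fit(y)
print(f"pixels: {y.size}, sample mean: {y.mean():.2f}")
print(f"robust GLM background: {fit.background:.3f} "
      f"(se {np.sqrt(fit.covariance[0,0])*fit.background:.3f}, "
      f"{fit.n_iter} iterations)")
print(f"hot-pixel weight: {fit.weights[np.argmax(y)]:.4f}")
```

prints

```
pixels: 72, sample mean: 18.68
robust GLM background: 4.865 (se 0.267, 8 iterations)
hot-pixel weight: 0.0030
```

The plain mean (18.68) is dragged far from the truth by the hot pixel; the
robust fit (4.865 ± 0.267) down-weights it to 0.3% and recovers the true
level.  The same comparison in aggregate, at a very weak background of
0.15 counts/pixel with no outliers at all:

```python
table = run_comparison([0.15], methods=("null", "tukey", "glm"),
                       n_replicates=2000, seed=1)
print(table[["method", "mean_normalized_difference",
             "zero_background_fraction"]].to_string(index=False))
```

```
method  mean_normalized_difference  zero_background_fraction
  null                    0.000000                      0.00
 tukey                   -3.217389                     99.65
   glm                    0.024285                      0.00
```

The Tukey filter sits more than three standard errors below the
no-handling estimate and returns a background of exactly zero for 99.65%
of these shoeboxes (it rejects every nonzero pixel); the robust GLM tracks
the unbiased no-handling estimate while retaining its resistance to
outliers.

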