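# landgrad

Dual-axis landscape gradients of human influence, with a single-season
occupancy engine for relating species detection/non-detection data to
those gradients.

## The problem

Urban-ecology studies usually compress landscape heterogeneity into a
single axis (percent impervious surface, housing density). Real
human-modified landscapes mix *three* poles — built, agricultural, and
natural cover — so one axis confounds two distinct kinds of human
influence. `landgrad` quantifies a categorical land-cover grid along
two interpretable, data-driven axes:

* **hard-to-soft** — from built/impervious ("hard") land to unpaved
  vegetated or agricultural ("soft") land;
* **brown-to-green** — within soft land, from agricultural ("brown")
  to natural forested/wetland ("green") cover.

It then asks how a species responds to both axes at once, using
occupancy models that correct for imperfect detection.

## The method

1. **Smoothing.** For each land-cover class *c*, extract the binary
   indicator (1 if the pixel is class *c*) and convolve it with a
   truncated Gaussian kernel (σ = 500 m by default, ~ a songbird
   breeding home range; 1500 m offered as a sensitivity scale). Each
   pixel then carries the kernel-weighted fraction z_c(x) ∈ [0, 1] of
   its neighbourhood in class *c*.
2. **Ordination.** Pool the pixels-by-classes matrix over all city
   windows and run PCA on the p × p Pearson *correlation* matrix, so
   eigenvalues sum to p and axis k explains 100·λ_k/p percent of the
   variance. Retain leading axes by the broken-stick rule
   b_k = (1/p)·Σ_{i=k}^{p} 1/i — with p = 15 classes the first
   broken-stick share is 22.1%, and axes are added until their
   cumulative variance passes it. Axes are oriented to fixed anchors
   (developed classes load negative on axis 1, forest classes positive
   on axis 2).
3. **Gradient surfaces.** Each pixel's axis value is the
   loading-weighted sum of its smoothed class fractions,
   s(x) = Σ_c z_c(x)·w_c.
4. **Occupancy.** Site i is occupied with probability ψ_i
   (logit-linear in city, HS, BG) and detected per visit with
   probability p_ij (logit-linear in city, scaled date, date², HS,
   BG). The likelihood marginalizes the latent occupancy state;
   candidate structures are ranked by AICc with Akaike weights, using
   a two-stage scheme (detection structure selected against the global
   occupancy structure, then occupancy structures against the best
   detection structure), and the selected model is checked with a
   parametric-bootstrap χ² test on detection-history frequencies.

No real land-cover or checklist data ship with the package: the
`synthland` generator builds seeded city-like landscapes (urban core,
agricultural belt, natural matrix) and `occupancy.simulate` draws
detection histories from known coefficients, so the whole pipeline is
exercisable and testable end to end.

## Worked example

```python
import numpy as np
from landgrad import (GridGeoref, LandscapeRecipe, generate_landscape,
                      smooth_stack, gradient_surface)
from landgrad.gradients import LandscapePCA

georef = GridGeoref(0.0, 6000.0, 30.0, 200, 200)   # 6 km window, 30 m cells
recipe = LandscapeRecipe({41: 0.5, 82: 0.3, 22: 0.2},
                         center_xy=(3000, 3000), urban_decay=1500,
                         autocorr_scale=150, seed=7)
land = generate_landscape(recipe, georef)
stack = smooth_stack(land, [41, 82, 22], sigma=150.0)
model = LandscapePCA(stack, anchor_map={1: ((22,), -1), 2: ((41,), 1)}).fit()
print(model.eigenvalues.sum(), model.n_retained)
hs = gradient_surface(stack, model, axis=1)
print(np.corrcoef(hs.values.ravel(), stack.layers[22].values.ravel())[0, 1])
```

prints

```
2.9999999999999996 2
-0.5853737090236574
```

— the three eigenvalues sum to p = 3 (correlation-matrix PCA), two
axes pass the broken-stick cut, and the oriented hard-to-soft surface
decreases where smoothed developed fraction is high (negative
correlation), as the anchor convention requires.

Fitting an occupancy model works the statsmodels way:

```python
from landgrad import OccupancyModel, simulate
import pandas as pd

sites = pd.DataFrame({"site_id": [f"s{i}" for i in range(1000)],
                      "city": "a",
                      "HS": np.random.default_rng(1).standard_normal(1000)})
data = simulate("HS", "1", [0.405, 0.8, -0.405], sites, visit_dates=4, seed=1)
res = OccupancyModel(data, psi="HS", p="1").fit()
print(res.params.round(3), res.converged)
```

```
[ 0.27   0.777 -0.329] True
```

recovering ψ ≈ 0.6 at the covariate mean (logit 0.405), the gradient
effect 0.8, and p ≈ 0.4 within sampling error.

A command-line front-end wraps every stage
(`landgrad simulate-landscape | smooth | gradients | surface | extract |
prep-checklists | simulate-occu | fit | select | gof | demo`); `landgrad
demo --out runs/demo` executes the whole pipeline on synthetic cities
and writes a seed-stamped report.

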