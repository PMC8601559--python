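# Methods

## Raster model

Grids live in projected map units (meters), origin at the top-left
corner, row-major, 0-based, pixel-center registered. Analysis windows
are snapped to the cell grid by `round(window / cell_size)` cells per
side (a 50 km window at 30 m is 1667 cells; the ratio is not integral,
so a rounding rule is unavoidable and this one is symmetric).
Point-to-pixel lookup is nearest pixel center — never bilinear,
because the extracted covariates are class-mixture fractions and
interpolation would smooth them a second time.

Two formats are supported: ESRI ASCII grid (parsed and written
directly; the format is a six-line header plus whitespace-separated
values) and single-band GeoTIFF via `tifffile`, carrying the
georeference in the ModelPixelScale/ModelTiepoint tags and nodata in
the GDAL_NODATA tag. Reprojection and datum handling are out of
scope; coordinates are taken as already-projected meters.

## Kernel smoothing

The "scale" of a Gaussian kernel smooth is interpreted as the standard
deviation σ in map units (the convention of common kernel-smoothing
utilities; 500 m default, 1500 m sensitivity scale). Weights are the
discrete Gaussian evaluated at cell-center offsets, truncated at 4σ
(discarding < 1e-3 of the mass, and keeping a direct-convolution
oracle affordable in tests) and renormalized to sum 1. The kernel
half-width in cells is `ceil(truncation / cell_size)`, so σ = 500 m on
30 m cells gives a 135 × 135 weight matrix.

Edge handling is a genuine free choice, so both policies are
implemented:

* `renormalize` (default): weights are rescaled to the kernel mass
  falling on valid in-grid cells. A constant field is a fixed point,
  and the per-pixel class fractions sum to one everywhere —
  the partition-of-unity invariant the ordination relies on.
* `zero_pad`: out-of-grid cells contribute zeros, matching plain FFT
  convolution; mass is conserved instead of normalized.

Nodata cells are excluded from both numerator and denominator and
propagate as missing.

## Ordination

PCA is run on the Pearson correlation matrix of the pooled
pixels-by-classes matrix (all city windows concatenated, accumulated
as streaming first/second moments so pooling is associative and
memory-flat). The correlation convention — rather than covariance —
is identified by the variance bookkeeping it implies: eigenvalues sum
to p and axis k explains 100·λ_k/p = 100·sdev_k²/p percent, which is
what the retention arithmetic below assumes. Classes with zero
variance have undefined correlations and are dropped with a warning
(p reduced), not imputed.

Axis retention uses the broken-stick rule, read as a *cumulative*
cut-off: retain the smallest m whose summed variance share exceeds the
first broken-stick proportion b_1 = (1/p)·Σ 1/i. With p = 15,
b_1 = 22.1%; a variance profile of 16.7, 11.1, 9.3 … retains exactly
two axes (16.7 < 22.1 ≤ 16.7 + 11.1). The phrase "broken-stick
cut-off" admits a per-axis reading (compare each v_k to b_k); the
cumulative rule is the one consistent with retaining two axes under
that profile, and the per-axis comparison can be recovered from the
model object's `broken_stick_proportions`.

Eigenvector signs are arbitrary, so axes are oriented by ecological
anchors: the summed loadings of the developed classes are forced
negative on axis 1 (hard end low — the surface then *increases*
hard-to-soft) and forest-class loadings positive on axis 2 (green end
high). Orientation is idempotent and never touches eigenvalues.

Gradient surfaces default to the weighted-average form
s(x) = Σ_c z_c(x)·w_c on the *raw* smoothed fractions. A true
standardized score mode ((z−mean)/sd weighted) is provided for
comparison; raw weighted averaging is the default because the surface
is meant as a map-unit description of composition, not a z-score, and
the two differ only by an affine transform per class.

## Synthetic landscapes

The generator emulates the gross structure of a mid-sized US city
window: an urban core whose developed-class intensity decays with
distance from the center, and a spatially autocorrelated mosaic of the
remaining classes. Each class receives a latent score field — white
noise convolved with the same Gaussian kernel machinery as the class
smoothing (one code path, one set of edge conventions), standardized
— developed classes add a radial Gaussian urban score, and each pixel
takes the argmax class. Per-class offsets are adjusted iteratively
(at most 100 sweeps, step proportional to the composition error) until
realized shares sit within 0.02 of the recipe targets; 0.02 keeps the
matching robust across seeds without over-fitting the latent fields.

What it does *not* emulate: road networks, hydrology, parcel geometry,
class-adjacency rules (crops next to pastures more often than next to
high-intensity development), or any specific real city. Tests passing
on these landscapes show the pipeline's algebra and invariants hold,
not that real NLCD gradients would reproduce any particular loading
pattern.

## Occupancy model

Standard single-season, zero-inflated Bernoulli likelihood with logit
links; ragged visit counts are supported throughout. The negative
log-likelihood and its analytic gradient are computed in log space
(`logaddexp` marginalization over the latent state), and maximization
is BFGS from a zero start with up to three seeded jittered restarts.
Convergence is declared only when the gradient max-norm is below 1e-4,
the central-difference Hessian of the NLL is positive definite
(standard errors come from its inverse), and no coefficient exceeds
|15| on the logit scale (a boundary guard: expit(15) is 1 to seven
decimals, so larger values indicate a degenerate fit such as
all-detected data). Non-convergence is recorded on the result object,
never raised — a selection run over 26 candidates must survive
individual failures, and with complex structures on modest data many
candidates legitimately fail.

AICc uses n = number of sites, the convention of standard occupancy
software; when n ≤ K+1 the correction is undefined and the model is
flagged non-converged. Akaike weights are normalized over converged
candidates only.

The formula language covers exactly the term algebra the candidate
sets need ({1, factor, continuous, date², a:b, a*b, a*(b+c),
a*(b*c)}), with treatment coding, alphabetical reference level, a
single intercept per submodel, and marginality enforced (date²
requires date; interactions require their mains). Under this
convention the ten-city design widths are 44 for ψ(city*HS+BG),
63 for ψ(city*(HS*BG)), 24 for ψ(1) and 53 for ψ(city*(HS+BG)), each
with the p(city*date+date²+HS+BG) detection structure.

The shipped detection candidate list is all 24 additive combinations
of {city} × {—, date, date+date²} × {HS} × {BG} minus the full
additive model, plus three single-interaction structures
(city*date+date²+HS+BG, city*date+HS+BG, city*HS): 26 total. The
occupancy list enumerates all 16 combinations of city-gradient
structure. Both are editable config artifacts; only their totals and
a handful of members are externally constrained, so the additive core
is the natural completion.

Two-stage selection fits every detection structure with the global
occupancy structure ψ(city*(HS*BG)) fixed, carries the AICc-best
converged detection structure into stage 2, and ranks the occupancy
structures with it.

## Goodness of fit

A MacKenzie–Bailey-style parametric bootstrap: sites are cohorted by
their visit count J (the classic test assumes equal J; cohorting
restores it for ragged data), all 2^J histories are enumerated per
cohort (capped at J = 14), expected counts are Σ_i Pr(history | x_i)
under the fitted model, sparse cells (E < 2) are pooled within cohort,
and χ² = Σ (O−E)²/E. The null distribution comes from refitting the
model to data simulated from its own MLE (the statistic must reflect
estimation noise, so each bootstrap dataset is refitted, not scored at
the original estimates); p is the share of bootstrap statistics at or
above the observed one and ĉ the observed-to-mean ratio. The test
statistic is seeded and exactly reproducible.

## Problem sizes

Defaults in tests and the acceptance script are chosen as desk-scale
study conditions: 120–200-cell grids for landscape fixtures, σ of
5–10 cells, 1000 sites × 4 visits for parameter recovery, 800 sites
for selection recovery, and GoF calibration at 60 sites × 3 visits
with 200 bootstrap draws over 100 replicates. These sizes put
Monte-Carlo error well inside the asserted tolerances while keeping
any single suite run in tens of seconds.

## Known limitations

* No reprojection; all inputs must share one projected CRS.
* PCA is pooled or per-stack; multi-group PCA variants, factor
  analysis, NMDS and rotations are out of scope.
* No effort covariates (duration, distance, observer) in the
  detection submodel, and no visit cap.
* Model-averaged prediction is not offered — weights are reported,
  predictions come from a single selected model.
* The GoF enumeration is exponential in J; cohorts beyond 14 visits
  raise rather than approximate.
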