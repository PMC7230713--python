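# Methods

## The measurement model

A partially scaled fish region imaged in reflectance is modelled as a
two-endmember linear mixture. Let `s(λ)` and `k(λ)` be the reflectance
fractions of scale-covered and skin-exposed surface, and `P` the scaling
rate in percent of region area. The noise-free ROI-mean spectrum is

```
μ(λ; P) = (1 − P/100)·s(λ) + (P/100)·k(λ),
```

the area-weighted pixel average. Since `s ≥ k` at every band, `μ` decreases
monotonically in `P` — the physical basis of the whole calibration. A
measured sample spectrum adds the three artifact families the pretreatments
exist to remove:

```
x(λ) = g · 100·μ(λ; P) + o + ε(λ),
```

with a per-sample multiplicative gain `g ~ N(1, scatter_slope_sd²)`
(surface geometry/moisture scatter, what MSC and SNV correct), a per-sample
additive baseline `o ~ N(0, baseline_sd²)` in percent reflectance (what the
first derivative removes), and per-band white noise
`ε ~ N(0, noise_sd²)` (what Savitzky–Golay smoothing removes). Reflectance
is carried in percent, the direct output of white/dark correction
`R = 100·(I_R − D)/(I_W − D)`; every downstream operation is either
scale-invariant or documents its scale.

## The synthetic generator

**Wavelength axis.** 360 uniformly spaced bands from ~386.4 to 1024.7 nm;
trimming to the 400–1024.7 nm analysis window leaves exactly 352 bands
(spacing ≈ 1.778 nm). The eight sub-400 nm bands exist so the trimming step
is exercised, mirroring the overlapping short-wavelength region real sensors
show.

**Endmembers.** Both curves share a slowly rising logistic base (reflectance
grows toward the NIR) with Gaussian absorption dips at 420 nm (porphyrins),
545 nm (metmyoglobin window) and 960 nm (water overtone), plus a small
seed-dependent long-period undulation. The skin dips are drawn deeper
(amplitude 0.06–0.09) than the scale dips (40–60 % of the skin depth):
exposed skin holds the water and pigments, while scales are largely
inorganic. This *differential absorption* matters structurally — if the two
endmembers differed by a flat offset, the scaling-rate direction in spectral
space would be collinear with the gain/baseline artifact directions and no
calibration, with any pretreatment, could separate them. The scale curve is
the skin curve plus a strictly positive smooth gap plus the dip-depth
difference, so `s ≥ k` holds by construction.

**Artifact magnitudes (defaults).** `scatter_slope_sd = 0.1`,
`baseline_sd = 2.0` (percent reflectance), `noise_sd = 0.05` (percent).
The noise default describes *ROI-mean sample spectra*: a 2 × 2 cm ROI is on
the order of a thousand pixels and measurements are made in triplicate, so
pixel-level sensor noise (~1 % reflectance) is divided by
`sqrt(n_pixels · n_replicates)` ≈ 50, leaving a few hundredths of a percent
per band; 0.05 keeps a visible noise floor for the smoothing step to act on.
Users simulating per-pixel cubes should pass a larger `noise_sd`.

**Scaling rates** are drawn uniformly on [0, 100] % (the full span of the
study design, which reports no other distribution); scenes draw a pixel mask
with exactly `round(coverage · n_pixels)` scale pixels. All randomness flows
through one integer seed and identical seeds give bit-identical arrays.

**What the generator does not emulate.** Real regional spectra differ in
shape between back, belly and tail; here regions differ only by seed (a new
endmember draw). There is no wavelength-dependent scatter, no stray light,
no detector nonlinearity, no spatial texture within a surface class, and
noise is homoscedastic across bands. Passing tests on this generator
therefore demonstrate that the pipeline's algebra and statistics are right
under the stated artifact model — not that any particular instrument will
reach the same figures.

## Pretreatments

* **SG**: least-squares local cubic smoothing on a 7-point window
  (`scipy.signal.savgol_filter`). Edges are handled by evaluating the
  terminal window's fitted polynomial at the boundary bands, so polynomials
  of degree ≤ 3 pass through unchanged everywhere; mirror padding was
  rejected because a mirrored polynomial is not its own continuation and
  breaks that exactness at the edges.
* **FD**: central difference `(R(w+1) − R(w−1))/(λ(w+1) − λ(w−1))` at
  interior bands — exact for quadratics on a uniform axis — with one-sided
  differences at the two boundary bands so the band count is preserved.
* **MSC**: ordinary least squares of each sample on the dataset-mean
  reference spectrum; the fitted affine distortion `(m_i, b_i)` is inverted.
  Correcting the reference itself is the identity. The reference is fitted
  on the whole region dataset (the convention for a fixed calibration
  transfer), and the fit object can be serialized and applied to new
  spectra.
* **SNV**: per-spectrum centring and unit-SD scaling (sample SD, `m − 1`
  denominator). Affine-invariant per sample by construction.

On this generator MSC and SNV produce nearly identical downstream models:
when every sample is an affine distortion of a shared shape the two
corrections coincide up to an overall affine map, which PLSR absorbs.

## Wavelength selection

* **SPA** grows a forward chain from *every* band as a candidate start: at
  each step all remaining band vectors (mean-centred across calibration
  samples) are projected onto the orthogonal complement of the chain and the
  largest-norm projection joins it. Every chain prefix is scored by
  internally validated regression RMSE — leave-one-out multiple linear
  regression with intercept by default (computed from the hat matrix), or
  k-fold-CV PLSR via `scorer="plsr"`. The selected subset is the best of
  the smallest size whose score is within 1 % (relative) of the global
  minimum — "the minimum number of wavelengths attaining the minimum RMSE".
  The default size cap is `min(n_samples // 3, 30)`, the usual
  three-samples-per-variable guideline for the scoring regression. A
  duplicated band can never be selected twice (its projection vanishes).
  SPA's candidate pool is chains, not all subsets, so it matches exhaustive
  best-subset search only when the RMSE minimum is well defined — e.g.
  noise-free responses that are exact linear functions of some band subset,
  where the agreement is structural; under noise, exhaustive search can
  always luck into subsets no chain contains.
* **RC** fits a full-spectrum PLSR (components cross-validated unless
  given), finds the local extrema — peaks *and* valleys — of the
  coefficient vector β, and keeps the `n_keep = 8` extrema of largest |β|
  in wavelength order (published CW counts for this method run 4–9). Fewer
  extrema than requested returns all of them with a warning.
* **2D-COS** orders the calibration samples by scaling rate, takes dynamic
  spectra as deviations from the perturbation-mean spectrum, and forms the
  synchronous map `Φ = Dᵀ D/(m − 1)` — symmetric and positive semidefinite
  by construction. CWs are the diagonal auto-peaks: local maxima with
  prominence above 5 % of the diagonal maximum (low enough to keep the weak
  auto-peaks, high enough to drop ripple), tallest first, capped at 8;
  boundary bands count when they dominate their neighbour. The perturbation
  reference is the mean over the series — the standard convention. The
  asynchronous map is not computed; it plays no role in selection here.

## PLSR and evaluation

Single-response NIPALS on centred data (no unit-variance scaling of bands —
the pretreatments already condition the spectra): weights
`w ∝ Xᵀy`, scores `t = Xw`, loadings `p = Xᵀt/tᵀt`, `q = yᵀt/tᵀt`, then
deflation. Successive scores are mutually orthogonal; the collapsed
coefficient vector `β = W(PᵀW)⁻¹q` reproduces latent-route predictions to
numerical precision, and at full rank it coincides with the least-squares
solution. Requesting more components than the data's effective rank raises
an error naming the achievable maximum.

The **60/40 split** ranks samples by response and assigns systematically
spaced ranks to the prediction set, so both sets span the response range; a
seeded random strategy is available. **Component counts** come from 10-fold
cross-validation with the one-standard-error parsimony rule (smallest count
within one SE of the minimising count, cap `min(20, rank)`) — pure-noise
responses get one component.

Metrics per set: `R² = 100·(1 − SSres/SStot)`, `RMSE` in percent scaling
rate, `SD` = sample SD of the *predicted* values on the fractional scale
(percent/100; both scales are exposed), `SE = SD/√n`, and
`RPD = 100·SD_pred/RMSEP`. That fractional-scale convention is verified by
the RPD identity against the published evaluation tables bundled in
`scalespec.published` (six cells reproduce to 2 dp; the remaining printed
cells carry independent rounding and are not asserted). Grading applies the
printed thresholds exactly: accuracy inaccurate/good/excellent at
`R²_P < 82`, `82–90`, `> 90` %; usability unusable/usable/excellent at
`RPD < 1.5`, `1.5–2`, `> 2`.

`run_model_matrix` evaluates the 16 models of one region — pretreatment on
the whole region dataset, one shared rank split, selectors run on the
calibration set only — and flags (rather than fails on) a selector that
returns no bands. `select_optimal_model` ranks CW models by prediction R²,
then stability `|RMSEC − RMSEP|`, then RPD; full-wavelength rows are
excluded since avoiding their 352 variables is the point of selection.

## Numerical choices and degenerate inputs

Reflectance correction refuses any band where the white and dark references
coincide, naming the band. SNV and MSC refuse zero-variance inputs; 2D-COS
refuses a constant perturbation; SPA raises when collinearity exhausts the
projection space before `k_min` bands. LOO leverages at 1 make a candidate's
score infinite rather than undefined. The SPA "minimum RMSE" tolerance
(1 % relative), the auto-peak prominence (5 % of the diagonal maximum) and
the NIPALS convergence guards (relative to the input norms) are all exposed
or documented constants.

## Problem sizes

The test suite and the acceptance script run the study at its native scale:
100 samples per region, 352 analysis bands, 60/40 split, three regions —
the full matrix takes a few seconds per region. Oracle suites use 200
small SPA instances (≤ 6 bands) and 50 PLSR instances (≤ 12 bands).

## Known limitations

* With the default 10 % multiplicative scatter, first-derivative models are
  the fragile corner: differentiation concentrates the gain artifact into
  exactly the high-slope bands that carry the scaling-rate signal, and at
  60 calibration samples FD characteristic-wavelength models hover around
  `R²_P ≈ 84–95` across endmember draws (full-wavelength FD models stay
  above 90). FD is also, by the same mechanism, hopeless when per-band white
  noise approaches the percent level — the method presumes smooth ROI-mean
  spectra.
* The optimal-model rule is a formalisation of a narrative choice; with
  near-tied candidates (MSC vs SNV here) the winner can switch between
  seeds.
* The published reference rows are values, not data: no spectra underlie
  them in this package, and nothing is fitted to them.
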