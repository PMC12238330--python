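# Methods

## Conjugate-view quantification model

The activity in an organ region is estimated from opposed planar views by
the geometric-mean method with effective attenuation correction:

    A = sqrt(I_A * I_B * exp(mu_e * T)) / C

**Assumptions.** The organ behaves as a single emitting slab inside a body
of thickness T along the projection axis; attenuation along the
anterior and posterior paths multiplies to exp(-mu_e * T) regardless of
organ depth (the property that makes the geometric mean depth-independent);
scatter and collimator response are absorbed into the calibration factor C.
The lung is treated as three regions (upper/middle/lower) because the
tissue column changes markedly from the rib-shadowed apex to the base, and
`effective_mu` is evaluated per region, never pooled across them.

**ROI statistic.** I_A and I_B are background-corrected count rates:
(mean in-ROI pixel − mean background pixel, floored at 0) × ROI pixel
count ÷ acquisition duration. Storing raw counts and deriving rates keeps
the images lossless; the floor prevents negative rates when the background
ROI is hotter than the organ.

**Thickness.** T comes from two cursor points on a single 45° oblique
view: Euclidean pixel distance × pixel pitch × an obliquity factor
(default 1.0 — the apparent thickness is taken as T; the factor is exposed
for users who prefer a geometric chord correction) ÷ 10 for cm.

**Recovery coefficients.** RC curves (measured on sphere phantoms,
typically spanning ~0.78–1.09 for planar imaging over 7.3–29.9 mm spheres)
are interpolated piecewise-linearly in diameter and applied as divisors.
Diameters outside the calibrated range clamp to the nearest knot with a
warning rather than extrapolate to unphysical values. RC correction is
optional per organ, since sphere-calibrated coefficients transfer only
approximately to organ geometries.

**Units.** C is fixed as counts·s⁻¹ per MBq so the formula is
dimensionally explicit with I as count rates. Radioactivity conversions
use the exact definition 1 mCi = 37 MBq; concentration units (X/ml)
convert with the same scale when both sides share the denominator.
Decay correction to a common reference time is off by default; a helper
applies lambda_phys = ln 2 / 192.5 h (the ¹³¹I physical constant) when
multi-session counts must share a time origin.

## Time–activity kinetics

Organ activity is modelled as A(t) = A1·exp(−λ1·t) (+ A2·exp(−λ2·t)),
fitted by least squares in activity space. A free biexponential has four
parameters and is refused for fewer than four time points — the standard
three-point schedule (24/72/168 h) is underdetermined for it, and silently
returning one of infinitely many interpolants would not be reproducible.
With three points the options are a monoexponential (default) or a
biexponential with one rate pinned (e.g. to lambda_phys).

Initialization is deterministic: the rate from the log-slope of the last
two points, the amplitude back-extrapolated from the first point; the free
biexponential peels the slow component off the tail first. Rates are
bounded below at 1e−6 h⁻¹. Cumulated activity uses the closed form
Σ (A_i/λ_i)(e^(−λ_i t0) − e^(−λ_i t1)), converted h→s; a trapezoid
integrator with an optional analytic physical-decay tail serves as the
model-free fallback. Because uncorrected counts are fitted, the fitted
rates are effective (biological + physical) rates and the default
integration window [0, ∞) needs no separate decay term.

Identifiability note: with 5% multiplicative noise the fast component of a
biexponential is only recovered reliably when early time points sample it
(the packaged check uses 2–168 h with seven points); sparse late-only
schedules leave λ1 poorly determined even though the fit converges.

## Dose-point-kernel dosimetry

The dose map is the true 2D convolution D = Ã ⊗ DPK with zero padding:
activity outside the field contributes no dose, which makes total-dose
conservation provable when the activity support stays at least half a
kernel from every border (sum(D) = sum(Ã)·sum(DPK)). Kernels are validated
before use: odd square grid, non-negative, central maximum, symmetric
under 90° rotation and mirroring within a tolerance relative to the center
value (an isotropic point source has no preferred direction, so
convolution and correlation coincide). `validate_kernel` reports the
center S-value and the energy coverage of every central crop; it warns
when the core (K−2)×(K−2) coverage is below 0.95 and can optionally reject
truncated kernels outright. The default geometry is 9×9 at 2.3976 mm — a
coverage/size trade-off for ¹³¹I beta+gamma kernels at planar pixel pitch —
and `kernel_size_study` quantifies the truncation deficit of smaller crops
on a uniform disc phantom.

Organ S-values are computed as mean self-dose over the mask per unit total
cumulated activity spread uniformly across the mask. Both this organ-level
S-value and the kernel center value are exposed, and the ML feature table
records which one it uses (the organ-level value, via `organ_s_value`).
Cross-organ dose is whatever the convolution support produces; no separate
cross-fire model is added (self-absorption dominates organ energy
deposition for ¹³¹I at these pixel sizes).

Kernel files: MetaImage grids or a whitespace text dialect with a 3-line
header (size, pixel size in mm, units) so Monte-Carlo exports can be
ingested from either route.

## Machine-learning dose regression

One pooled model maps the feature vector (I_A, I_B, thickness, S-value,
mu_e, BMI, age, one-hot organ) to organ dose; per-organ metrics are
reported from the pooled model rather than training per-organ models,
because the feature list already carries the organ identity. Pipeline
order: clean (drop rows with missing target; mean-impute — or interpolate
along patient-then-organ order — missing features; remove |z| > 3
outliers), split 75/25 with a fixed seed, fit normalization constants on
the training split only (min–max for the two count features, z-score for
the rest), transform both splits with the saved constants. A transformed
table carries a `normalized` flag so re-applying the saved constants is a
no-op — the contract that makes train/test leakage structurally
impossible rather than a convention.

Model defaults: MLP with hidden layers (6, 6, 6), ReLU, adam at learning
rate 1e−3, batch size 50, L2 penalty 1e−3, early stopping with patience
200 (shorter patience occasionally strands the small network in a poor
optimum on the synthetic cohort); SVR with RBF kernel, C = 100, γ = 10 on
the normalized features; decision tree with minimum leaf size 5 and at
most 21 leaves (20 internal splits); linear regression solved by
minimum-norm least squares (no singular-value cutoff, so coefficients on
designs mixing count scales ~10² with S-value scales ~10⁻⁵ are recovered
exactly), with an optional iteration-capped L-BFGS path that column-scales
the design before optimizing. Tree and linreg are bit-deterministic;
MLP/SVR are deterministic given the seed.

Evaluation: MAE, MSE, RMSE overall and per organ (RMSE² ≡ MSE by
construction; MAE ≤ RMSE by the power-mean inequality). Percent error is
signed, (pred − ref)/ref × 100. External validation uses a Shapiro–Wilk
test on the paired differences to choose between the paired t-test
(normal) and the Wilcoxon signed-rank test; identical vectors return a
degenerate flag with p = 1. Under a normal null this adaptive procedure's
empirical type-I error sits near the nominal 0.05 (the Shapiro gate
occasionally routes a normal sample to Wilcoxon, which is similarly
calibrated under symmetry).

## Synthetic phantoms — what they do and do not emulate

The forward projector is deliberately the *minimum* physics that makes the
conjugate-view formula exactly invertible: each elliptical organ is a slab
at one depth, anterior/posterior rates are C·A·e^(−μd) and
C·A·e^(−μ(T−d)), the posterior image is stored detector-oriented (180°
rotated), a uniform mid-slab background is added symmetrically (so mean
background subtraction removes it exactly), and Poisson noise is applied
per pixel when enabled. The default three-organ phantom (liver 120,
spleen 30, thyroid 60 MBq; C = 1000 counts·s⁻¹/MBq; 600 s acquisition)
yields organ counts well above 10⁵, so Poisson recovery errors are at the
few-per-mil level. The oblique view encodes the body thickness as a bright
chord of known endpoints.

Not emulated: scatter, septal penetration, collimator-detector response,
organ overlap along the projection axis (overlap in-plane is permitted and
flagged), 3D depth structure, patient motion. Passing phantom-recovery
tests therefore demonstrates the correctness of the quantification
algebra and its implementation — not clinical accuracy on real images,
where those confounds dominate.

The kernel generator uses an exponential radial profile k(r) =
amplitude·e^(−r/range) — kernels are interchangeable inputs here, and the
generator's job is to produce grids that satisfy every kernel invariant,
not to reproduce a specific ¹³¹I beta/gamma spectrum. Cohort generation
draws age 20–80 y, BMI 17–40 kg/m², thickness 15–35 cm, mu_e 0.09–0.13
cm⁻¹, count rates lognormal (median 200 cps, σ = 0.35), S-values
log-uniform 2e−5–8e−5 Gy/(MBq·s). The linear generator's target is affine
in the features (coefficients stored in the table metadata for recovery
tests); the nonlinear generator's target is the quantification physics
chain itself — conjugate-view activity × physical-decay residence time ×
S-value × organ geometry factor × inverse-BMI habitus factor — plus
Gaussian noise (σ = 1 Gy against doses of tens of Gy), so learning it
means learning the multiplicative structure a dosimetry regressor must
capture.

## Numerical choices and degenerate inputs

- MetaImage DimSize is (cols, rows); in-memory grids are row-major
  (rows, cols). Supported element types: 8/16/32-bit integers, 32/64-bit
  floats; anything else is refused naming the offending tag.
- "Rotate the posterior 180°" is a flip along both axes (a transpose would
  change the aspect ratio); the operation is an involution.
- Constant features under z-scoring pass through unchanged with a warning
  (dividing by a ~1e−17 floating-point SD would explode them); constancy
  is detected with a relative tolerance.
- Convolution uses scipy's direct method via `convolve2d`; tiny negative
  values from floating-point cancellation are clipped to zero so dose maps
  stay non-negative.
- Coincident thickness cursor points, empty masks, empty attenuation
  lists, zero reference doses, and t_end ≤ t_start integration windows all
  raise explicit errors rather than returning NaN.

## Problem sizes

The packaged checks run on 128×128 phantoms (100 Poisson replicates),
50 random convolution pairs up to 32×32 maps with up to 13×13 kernels,
500-record cohorts, 200–500 replicate statistical calibrations, and
200k-point quadrature grids. These sizes give stable estimates of every
reported quantity while keeping the full suite under a minute of compute.

## Known limitations

- No organ-overlap or scatter correction in quantification; mu_e values
  are config inputs, not derived from CT.
- The biexponential refusal on three points is a deliberate deviation from
  common field practice of fitting anyway; users who need the old
  behaviour must pin a rate.
- The MLP is a scikit-learn `MLPRegressor`; its activation is plain ReLU
  (the leaky variant is not available in that implementation).
- Dose maps are 2D pixel doses; no 3D voxel dosimetry or tissue-density
  scaling.
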