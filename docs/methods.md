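# Methods

`cocomorph` implements, as a tested and reusable pipeline, a morphometric
analysis of coccoliths imaged under circularly polarized light: simulate
micrographs of model coccoliths with known geometry, measure length,
thickness, mass and shape per coccolith, estimate the k_s shape factor, and
test whether length and thickness scale isometrically. This note documents
the models, the defaults and their rationale, the numerical choices, and
what the synthetic benchmark does and does not establish.

## Optical model

A thin birefringent calcite plate of thickness *t* (μm) between crossed
circular polarizers retards transmitted light by Γ = 1000·Δn_eff·t
nanometres. In the first interference order the image grey value rises
monotonically with Γ, which makes grey invertible to thickness, and hence to
per-pixel calcite mass

    m_px = t · A_px · d,     d = 2.71 pg μm⁻³ (calcite),
                             A_px = 0.0003 μm² (pixel area).

The forward curve is modelled as a single-wavelength crossed-polarizer
intensity

    g(Γ) = offset + (gain − offset) · sin²(π Γ / λ),   λ = 550 nm,

fit through reference retardation films (31 nm and 129 nm by convention)
and restricted to Γ ∈ [0, λ/2], where it is strictly increasing. A
piecewise-linear calibration through the reference points is available as an
alternative. Real calibrations derive from the grey rendering of a
Michel-Lévy colour chart; the sin² curve is the invertible single-wavelength
analogue and is adequate in the first-order grey regime. Greys below the
dark offset (background noise) clamp to zero retardation with a logged
count; greys above the gain are outside the first-order regime and are an
error.

Effective birefringence defaults to calcite's maximum, Δn_eff = 0.172, and
is configurable: real coccoliths present a distribution of c-axis
orientations, so the effective value of a particular instrument is an
empirical constant absorbed by its calibration. Because the same constant
is used for rendering and measurement, recovery tests are unaffected by its
exact value.

**Bit depth.** Images render at 16-bit by default (8-bit optional). Under a
single grey wavelength, an E. huxleyi-scale retardation of ~12 nm spans
only ~1 grey level of an 8-bit scale — quantization would destroy the
signal that a full-colour chart calibration distributes over three camera
channels. At 16-bit the same signal spans ~260 levels and quantization is
negligible against the noise floor.

## Synthetic coccoliths

A model placolith is two concentric ellipses: an outer shield of major axis
L (aspect ratio AR = major/minor ≥ 1) and a central-area opening at a
linear fraction f_c of the outer semi-axes. On the shield annulus the
thickness profile in normalized elliptical radius u ∈ [0, 1] is

    t(u) = T_s · (floor + (1 − floor) · sin(π u)^p),

zero inside the central area. Defaults: f_c = 0.4, AR = 1.25, p = 8,
floor = 0.3. No published thickness profile exists for these species, so
the profile is configurable and only integrated quantities (mass, mean
thickness, skewness) are treated as meaningful. The defaults were chosen
for two physical reasons: the non-zero rim floor gives the particle a sharp
step edge, as real shields have finite edge thickness, which lets an edge
detector localize the boundary at the true rim; and the peaked profile
(p = 8) concentrates thick pixels in a narrow mid-shield band, reproducing
the right-skewed per-pixel thickness distributions (g₁ ≈ 0.4–0.9) reported
for real coccoliths. Per-coccolith peak thickness is rescaled so the
discrete map's mean thickness over its support equals the sampled target
exactly (the map is linear in T_s).

Ground truth per particle is computed from the discrete map itself:
mass = d·A_px·Σt exactly, area = support pixel count × A_px, mean
thickness = mass/(d·area), skewness over support pixels (central-area zeros
included), k_s = m/(L³·d).

**Populations.** One sample draws n coccoliths (default 30, the study
convention) with lengths from a normal truncated at zero, mean optionally
shifted linearly in salinity. Mean-thickness targets follow the coupling
mode: `isometric` (T̄ = c·L, the k_s model's assumption), `allometric`
(T̄ = c·L^b), or `decoupled` (T̄ ~ N(T₀, σ_T), independent of length — the
pattern the E. huxleyi data show). The default study design reproduces the
published experiment: 8 strains × 3 salinities (25/34/44), per-cell mean
lengths 2.5–3.4 μm (E. huxleyi) and 4.5–5.1 μm (G. oceanica), mean
thicknesses 0.064–0.158 μm, population sd back-computed from the printed
95 % CIs (CI·√30/t₀.₉₇₅,₂₉). E. huxleyi cells default to decoupled
thickness; the G. oceanica cells are isometric at c = T̄/L̄.

**Table mode vs image mode.** Image mode renders non-overlapping particles
on a grid, adds Gaussian grey noise (default sd 40 on the 16-bit scale) and
quantizes; reference-film patches can be rendered in-frame. Table mode
bypasses imaging for fast statistical work and instead perturbs the ground
truth with the study's stated standard (1σ) measurement noise: 0.1 μm
length, 0.0035 μm thickness, 8.5 % relative mass (half the quoted 95 %
values). All randomness flows from one master seed through per-cell spawned
child streams, so studies are exactly reproducible.

## Measurement

Segmentation is Canny edge detection (Gaussian-derivative gradient with
hysteresis; defaults σ = 1.4 px, thresholds 8×10⁻⁴ / 1.5×10⁻³ on the
[0,1]-normalized image, chosen so the high threshold sits ~3σ above the
smoothed noise-gradient floor yet below the weakest rim step in the study
range). Edge maps are morphologically closed, filled and eroded back one
step so the mask boundary tracks the edge locus; the image is padded with
its median before edge detection so border-cut particles still close.
Particles are filtered by area (0.5–100 μm²) and, by default, border
contact. Central-area holes are retained as zero-thickness pixels inside
the outer contour.

Per particle: length and width are the moment-ellipse major/minor axes
(maximum Feret diameter optional); mean thickness is the mean calibrated
pixel thickness; mass is d·A_px·Σt, so m = d·area·T̄ holds to machine
precision; skewness is the biased Fisher–Pearson g₁ = m₃/m₂^{3/2} of the
within-mask thickness values (raw grey optional — the two differ under the
nonlinear calibration; thickness is the default because it is the physical
quantity).

On zero-noise synthetic images the pipeline recovers length within ~1 px,
mean thickness within ~1.5 %, and mass essentially exactly; with default
noise, mass carries a ~+2.5 % bias from clamp rectification of dim pixels,
well inside the stated mass uncertainty.

## Uncertainty budget

First-order (quadrature) propagation, reported at 95 % confidence (×1.96),
from four 1σ components: grey noise sd (default 40), calibration relative
sd (0.05), pixel-size relative sd (0.005), and edge localization (4 px).

* length: two independently localized edges plus the pixel-size term;
* mean thickness: calibration term plus grey noise averaged over the N
  mask pixels (independent sensor noise);
* mass: calibration and pixel-area terms plus the grey-noise term taken as
  **common mode** (illumination variation does not average over a
  particle), converted to thickness through the local slope of the
  calibration curve at the particle's mean retardation — so thin, dim
  particles carry larger relative mass uncertainty, reproducing the
  size-dependence of the published 13–20 % band.

With defaults, an E. huxleyi-scale particle (T̄ ≈ 0.07 μm, ~10⁴ px) gets
u_l ≈ 0.2 μm, u_T ≈ 0.007 μm and u_m/m ≈ 14–19 %; empirical coverage of
ground truth by measurement ± u on noisy renders exceeds 90 %. The exact
partition among noise sources is not published; these defaults are the
package's own budget, validated by that coverage check. A measured
difference counts as *resolved* only when it is at least twice the stated
uncertainty.

## k_s model and audit

The shape-factor model m = k_s·l³·d presumes isometric growth. The package
computes per-coccolith k_s = m/(l³·d) and two sample-level estimators: the
mean of per-coccolith ratios (with t-based 95 % CI) and the ratio of means
m̄/(l̄³·d). They agree exactly on identical coccoliths and diverge by
≈ 3·cv² (Jensen's inequality on l³) under length dispersion — about 3 % at
the study's cv ≈ 0.10 — so both are always reported; printed rounded
sample tables are generally reproduced by the ratio-of-means form. Model
bias is 100·(estimated − measured)/measured and is scale-invariant in
length; applying a literature k_s of 0.05 to material whose measured shape
factor is 0.021 overestimates mass by 138.1 % (~140 %). Exponential-phase
growth rate is μ = (ln c₁ − ln c₀)/t.

## Statistics

One-way fixed-effects ANOVA per strain and metric; significant ANOVAs are
followed by all-pairs Tukey HSD with Tukey–Kramer standard errors and
adjusted p from the studentized range distribution (scipy's numerically
integrated CDF; validated against a Monte-Carlo simulation of the range of
k normals over a pooled χ scale and against the k = 2 pooled-t identity).
Pairwise differences are additionally flagged by the 2×-uncertainty
resolvability rule.

Within each sample, OLS regressions of thickness, mass, skewness and
aspect ratio on length are screened by a global validation of the
linear-model assumptions: four directional statistics — residual skewness,
residual kurtosis, link misspecification (score test for a squared-fitted
term) and heteroscedasticity (squared residuals on fitted values) — each
asymptotically χ²(1), summing to a global χ²(4) statistic. Because the
statistics are computed on residuals, they are standardized with the
residual degrees of freedom m = n − 2 (exact null moments of g₁ and g₂ at
size m; m·R² for the score components); a level simulation at the study's
n = 30 confirms type-I error within [3 %, 7 %] at nominal 5 %. Independence
is not testable from one unordered sample and is reported as assumed.
Policy on violation: refit on the natural-log log-log scale; if the refit
still violates, keep the untransformed fit and flag it unfixable.
Influence diagnostics flag observations whose externally studentized
residuals leave the pointwise 95 % normal quantile–quantile envelope
(se via order-statistic asymptotics); flagged points are reported, never
removed. On clean data this envelope is conservative — studentization pins
the residual scale, so false flags are rare — while multi-σ outliers are
caught reliably.

Non-finite measurements are dropped with a logged count before any test.
Zero-variance groups yield F = 0, p = 1 by convention.

## Problem sizes used in the test and acceptance suites

The shipped suites run the full default design (24 samples × 30
coccoliths) in table mode, image-mode studies of 10–24 rendered particles,
a 2000-replicate level simulation at n = 30, 15 replicates of the
three-salinity decoupled study for the qualitative-reproduction check, and
a 50 000-draw Monte-Carlo oracle for the studentized range. These sizes
give stable pass/fail behaviour at interactive runtimes.

## Known limitations

* The geometric model is an idealized placolith: no malformation, no
  bridge structures, no overlapping particles, no 3-D crystal optics or
  c-axis orientation effects; segmentation is not watershed-based and will
  not separate touching coccoliths.
* The sin² grey model is a single-wavelength stand-in for a colour-chart
  calibration; gamma handling is self-consistent (calibration and
  rendering share the encoding) rather than a model of any specific
  camera pipeline.
* Passing recovery tests on this generator shows the inverse pipeline is
  correct under the stated imaging model; it does not certify accuracy on
  real micrographs, whose noise, background and morphology are richer.
* Growth-rate inputs (exponential-phase endpoints) are taken as given;
  the package does not detect the exponential phase from time series.
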