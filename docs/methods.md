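# Methods

This package reimplements, as tested library code, the quantitative
analyses used to characterise an eye/slit structural defect in 20-month
ripened hard cheese: opening morphometry from slice scans, ¹H CPMG
relaxometry decomposition, penetration-test texture indices, capillary-
electrophoresis proteolysis ratios, and a variance-gated two-sample
comparison scheme. Because the physical cheeses are not available, a
synthetic-data module generates every input with known ground truth; the
published group summaries (stored in `caseoscan.reference`) act both as
inputs to the statistics and as planted values for recovery benchmarks.

## Opening morphometry (imaging)

A scanned slice is modelled as a bright paste field over a black backdrop,
with openings as dark holes strictly interior to the paste. Segmentation:

1. The backdrop is identified by flood-filling dark pixels (< 0.1
   intensity) connected to the image border; the cheese section is the
   largest remaining connected component, and its pixel count fixes the
   section area.
2. A global Otsu threshold on the section's intensities separates openings
   from paste. If the threshold lands above 0.75 × the section's median
   intensity, the histogram is unimodal — no openings (the normal case for
   sound cheese) — and the section is reported hole-free. This guard is
   needed because Otsu always returns *some* threshold, even on pure
   paste texture noise.
3. Connected components (8-connectivity) touching the section rim are
   discarded, as is anything below the minimum-area filter
   (default 0.2 mm²; the smallest opening reported for these cheeses is
   0.39 mm², so the default removes scanner specks without touching real
   openings).

Each region's same-second-moments ellipse is computed from the covariance
eigenvalues λ₁ ≥ λ₂ of its pixel coordinates: major axis a = 4√λ₁, focal
distance c = 4√(λ₁ − λ₂), eccentricity e = c/a = √(1 − λ₂/λ₁). This is the
standard region-properties convention (verified against
`skimage.measure.regionprops` in the tests, which agree to 10⁻⁶). An
opening with e < 0.9 is an eye; e ≥ 0.9 (boundary included) is a
crack/slit. Porosity is 100 × Σ opening areas / section area; size
percentiles (D25/D50/D75) interpolate linearly between order statistics
(the "type 7" rule — the convention is a package choice, as none is
implied by the problem). Areas are converted to mm² (pixel count /
resolution², default 236 px·cm⁻¹ = 600 dpi) before any statistic.

Degenerate inputs: an all-backdrop image raises "no cheese section"; a
single-pixel region has no defined ellipse and raises; an empty opening
list yields porosity 0 but no size distribution.

## CPMG relaxometry

Echo times follow t_k = 2τ(k + 1) for sample k (τ = interpulse
half-spacing, default 80 µs; 30,000 points span 0.16–4800 ms). The forward
model is S(t) = S₀ Σᵢ (pᵢ/100)·exp(−t/T₂ᵢ).

**Discrete fit.** Nonlinear least squares by variable projection: the
optimiser searches log T₂ (bounded to [t₁/5, 2·t_max]) while amplitudes
are solved at every step by non-negative least squares, which enforces
positivity by construction and reduces the search dimension to the number
of components. Multi-start: seeds {1, 10, 50, 170} ms — log-spaced values
bracketing the four populations of long-ripened cheese — plus 4 random
log-uniform restarts (seeded); best residual wins. Abundances are
renormalised to 100 % and populations labelled A–D by increasing T₂.
Components that collapse to < 1 % abundance are reported as degenerate
rather than hidden. Echo trains are decimated before fitting by averaging
in ≤ 2000 log-spaced time bins with √count residual weights: early echoes
are kept verbatim (bins hold one point each out to ~31 ms) while the long
tail is noise-averaged, which preserves the least-squares solution while
cutting the problem size 15-fold.

**Quasi-continuous spectrum.** Non-negative Tikhonov inversion of the
Laplace kernel K(t, T₂) = exp(−t/T₂) on a log-spaced grid (default 200
points over 0.1–3000 ms), with a second-difference smoothness penalty.
The weight defaults to a generalised-cross-validation choice computed on
the unconstrained ridge surrogate. A light uniform-penalty iteration
(2 passes) then rescales the penalty rows down where the current iterate
is sharply curved; without it a single global weight visibly displaces the
mode of the small fast population (A, ~5 % at ~1.5 ms) toward shorter
times. Spectrum modes are local maxima with prominence ≥ 2 % of the
tallest peak (a floor that separates real populations, whose peaks are an
order of magnitude larger, from noise ripples). Population areas integrate
the density between cut points, by default the deepest valley between
consecutive modes.

Numerical caveat: the summed density estimates S₀ and is conserved within
2 % for any smoothing up to ~30× the GCV choice. At absurdly large
weights the flat solution acquires mass at T₂ below the first echo time,
where the data carry no constraint, and the total inflates; conservation
is therefore only claimed over the operating range in which the penalty
actually flattens the density (tests cover weights up to 30).

## Penetration texture

True strain ε = ln(h₀/(h₀ − Δh)) and true stress δ = F/A with A the
constant cross-section of the cylindrical probe, π(d/2)² (d = 3 mm
default) — the standard convention for a cylindrical indenter, and the
only one that makes δ = F/A well defined without a contact model. h₀ comes
from configuration, not from the curve. Young's modulus is the
least-squares slope over ε ∈ [0.005, 0.05], with the upper end shrunk
until R² ≥ 0.99 (at least 5 points); failure to reach that bar returns the
best-effort slope flagged. Fracture is the first local stress maximum
followed by a ≥ 10 % relative drop within the next 0.02 strain; the
reported point is the sample immediately preceding the steepest
single-step drop in that window. Anchoring on the drop rather than on the
local maximum matters because realistic curves flatten near the peak:
with 1 % force noise the first qualifying ripple can precede the true
collapse by most of the lookahead window (a 6 % strain error in our
benchmarks), while the steepest-step rule recovers the planted fracture
strain to within the sampling step.

## Group statistics

The design is two groups of three replicate cheeses; every published
variable is mean ± SD. Comparison scheme: an F-test of variance equality
(statistic = larger/smaller sample variance, (n−1, n−1) df, two-sided p by
doubling the upper tail) gates at α = 0.05 between Student's
pooled-variance t-test and the Welch–Satterthwaite t-test, two-sided at
α = 0.05. The gate's α is set equal to the global α since no separate
value is implied. Summary-statistics input is first-class — (n, mean, SD)
are sufficient for both tests — and raw-sample input reduces to it
exactly. No multiple-testing correction is applied by default, matching
the source analysis; a Holm adjustment is available but off.

One published SD is a bound, not a value: the population-A abundance of
the non-defective group is "< 0.01". It is stored as 0.009; any value in
(0, 0.01) leaves that comparison heterogeneous-gated and non-significant,
so the choice does not affect conclusions.

Proteolysis: corrected peak area = raw area / migration time, exactly;
the four casein-fragment ratios are ratios of corrected areas, with the
αs(f1–23) denominator the summed corrected area of the αs₁ and αs₀
parents. Plate counts transform as log₁₀(count × dilution / volume), with
zero counts flagged below-detection rather than −∞; a per-gram convention
is exposed alongside per-mL since the homogenate basis is ambiguous in
routine reporting.

## Synthetic fixtures

Every generator returns the fixture plus a `SyntheticTruth` carrying the
planted parameters and seed; same seed, same bytes.

- **Slice images**: hard-threshold (anti-alias-free) rasterisation of
  ellipses (axis ratio r ≥ 0.1) or capsule slits (r < 0.1), intensity
  0.05 on paste 0.75 over backdrop 0.02, additive Gaussian pixel noise
  (default σ = 0.02, a typical flatbed-scan noise floor); random
  non-overlapping placement with 100 retries. Hard thresholding keeps
  planted areas countable; pixelation errors stay inside the 3 % imaging
  recovery budget for openings ≥ 0.5 mm². The planted eccentricity of an
  axis-ratio-r ellipse is √(1 − r²). The 12-ellipse benchmark pairs the
  near-threshold ratios (0.46, 0.40 → e = 0.888, 0.917) with the largest
  areas so pixelisation cannot flip their class.
- **Decays**: forward model plus additive Gaussian noise of constant
  σ = S₀/SNR (default SNR 1000, representative of a 12-scan benchtop
  CPMG; magnitude bias is negligible at that SNR).
- **Penetration curves**: stress linear (E·ε) through the modulus window,
  then a monotone cubic Hermite bend (slope clamped by the
  Fritsch–Carlson bound, zero slope at the peak) to the fracture point,
  then a 60 % stress drop; inverted to force–displacement through the
  strain/stress definitions, with optional multiplicative force noise.
- **Group samples**: normal draws; with `exact=True` the draws are
  affinely rescaled so sample mean and SD (ddof = 1) match the targets to
  machine precision — the tool used to reconstruct raw replicates behind
  a published mean ± SD.
- **Peak tables**: corrected areas back-computed from random migration
  times so the planted ratios come out exactly.

What the fixtures do *not* emulate — rind, crystals and shading in scans;
magnitude noise, baseline drift and T₁ contamination in decays; serrated
fracture and probe friction in texture — bounds what passing tests show:
recovery holds for the idealised acquisition physics, not for every
instrumental artefact of real data.

## Study orchestration and problem sizes

`pipeline.run_study` computes per-replicate indices first, then group
mean ± SD (n = replicates), then the gated comparison per variable present
in both groups; partially filled designs skip the affected comparisons
with a logged warning. Reports are plain CSVs plus a YAML run log;
regeneration is byte-identical.

The bundled analysis scripts use three replicates per group, 100 × 100 mm
sections at 236 px·cm⁻¹, 30,000-point decays at SNR 1000, and 20
Monte-Carlo repeats for the relaxometry benchmark — the study's own
acquisition geometry throughout. In the end-to-end emulation the
borderline T₂D marker (p ≈ 0.047 from exact summaries) can drift just
above 0.05 because the fitted replicate values add fit noise to the
planted between-replicate spread; the exact-summary route reproduces the
published marker set identically.

## Known limitations

- 2-D morphometry only: no stereological correction from slice sections
  to wheel volume, and no X-ray 3-D reconstruction.
- The spectrum inversion approximates the full uniform-penalty scheme
  with a GCV-chosen global weight plus two reweighting passes; peak
  *positions* are accurate to ~15 % at SNR 1000, so the discrete
  multiexponential fit remains the quantitative route for T₂ values and
  abundances.
- The F-gate with n = 3 has little power; this mirrors the source
  procedure rather than a recommendation.
- Eccentricity of very small regions (tens of pixels) is biased by
  pixelation; the 0.02 accuracy claim holds for regions ≥ 500 px.
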