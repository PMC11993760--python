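# Methods

## The model

Facial skin topography is represented at two scales on a single periodic
1D cross section h(x) (heights in µm, air above, medium below, crista
reference plane at h = 0):

* **Macro texture** — furrows (sulcus cutis) of width `W_V` and depth `H`
  repeating with period `W`. Each furrow is a flat-bottomed groove whose two
  walls are quarter ellipses with vertical semi-axis `H` and horizontal
  semi-axis `W_V/2`, meeting smoothly (horizontal tangent) at the bottom.
* **Subvisible micro texture (SMT)** — a train of upper-half-ellipse bumps
  of peak-to-valley height `u_h` and base period `u_w` on the ridge tops
  (crista cutis). The train starts at the furrow edge; the last bump may be
  truncated at the far edge of the period, which renders as one steep
  polyline segment there. The ripple rides on the flat crista top only,
  not on the furrow walls.

The medium is uniform and non-absorbing with refractive index `n`
(skin 1.40, PMMA 1.49); subsurface scattering, chromophores and multilayer
transport are outside the model. The dimensionless controls of all
empirical results are `u_w/u_h` (ripple aspect ratio; small = fine,
strongly scattering texture) and `W_V/W` (furrow fraction).

Six published parameter presets are bundled (four skin replica samples, the
sandblasted PMMA plate SB6, and the molded plate HD6). The published HD6
row admits two readings of its ripple parameters, so both `hd6_narrow`
(u_h = 18.85, u_w = 256.4) and `hd6_wide` (u_h = 18.8, u_w = 5256.4) are
provided; neither is treated as canonical anywhere in the code. Likewise
the u_w/u_h values quoted in running text (15.2, 21.9, 11.8, 25) do not
all match the tabulated quotients; both sets are exposed
(`REPORTED_U_RATIOS` vs `SurfaceParams.u_ratio`) without reconciliation.

## Ray tracer

A bespoke 2D geometric-optics tracer (numba-compiled kernel) computes
diffuse reflection (air-side illumination) and diffuse transmission
(medium-side illumination) on the sampled profile:

* The analytic profile is sampled to a uniform polyline; the default
  resolution is ≥ 1000 segments per macro period and ≥ 40 per ripple
  period (a floor of 20 per `u_w` is enforced). Intersections use periodic
  wrap in x and an epsilon of 1e-6 µm against self-re-hits.
* At every hit the ray splits **deterministically** into a reflected and a
  refracted child weighted by the unpolarized Fresnel power coefficients
  (mean of s and p; the refracted child is omitted under TIR). Monte Carlo
  randomness enters only through the seeded launch positions, uniform over
  one macro period — this gives low variance and exact reproducibility.
* Children terminate when they escape the slab above max(h) or below
  min(h), fall below `power_cutoff` (default 1e-4 of the parent primary
  ray's launch power), or exceed `max_depth` (default 20) bounces;
  terminated power is reported as `residual`, never dropped. Across all
  bundled presets, modes and angles 0–60°, the residual stays below
  3e-4 and R + T + residual = 1 to ~1e-12.
* Exit power is binned conservatively by global exit angle (default 1°
  bins over [-90°, 90°]). The scattering angle carries the sign of the
  horizontal direction of travel, so the specular/Snell peak of a +45°
  incidence sits at +45°/+Snell — the convention under which the
  flat-surface transmission lobe centers on the Snell angle.
* Rays that march more than `64 × samples_per_period` cells without
  resolving (extremely grazing paths) are also counted into the residual.

The flat-surface limit reproduces closed-form Fresnel reflectance to
machine precision at all tested angles, and skin-side illumination beyond
the critical angle asin(1/1.4) ≈ 45.58° returns exactly zero transmission.

## Lobe fitting

Angular lobes are fitted with A·exp(-(θ-µ)²/2σ²) by unweighted nonlinear
least squares (scipy `curve_fit`, LM, tolerances 1e-14 so shift
equivariance holds to 1e-9). Initialization: A₀ = max intensity, µ₀ =
argmax bin (or a caller-fixed center), σ₀ = intensity-weighted angular
standard deviation. Zero bins stay in the loss (they constrain σ); powers
are deterministic fractions, not counts, so Poisson weighting is not used.
µ is a free parameter by default. Distributions with fewer than five
nonzero bins raise a degenerate-fit error; an optional flag excludes a
single bin more than 100× its neighbors (an unscattered specular remnant),
off by default. Goodness is the coefficient of determination; near-uniform
input converges to goodness ≈ 0 and is thereby flagged poor.

## Parameter recovery from cross sections

`parameterize_profile` inverts a measured or synthetic cross section into
the five parameters. Design choices where the procedure was genuinely
open:

* **Furrow detection** — contiguous runs deeper than 50% of the robust
  (1st–99th percentile) height range. A run set counts as macro texture
  only if its mean depth exceeds 5× the robust amplitude of the remaining
  (crista) signal: true furrows are an order of magnitude deeper than the
  ripple, whereas ripple valleys detected this way have depth of the same
  order (~3×) as the surrounding amplitude. Otherwise macro parameters are
  reported absent and the whole section is treated as ripple.
* **Furrow width** — a run measured at the 50% level under-reports an
  elliptical-walled groove's width by ~15%, so each run's extent is
  refined at a crossing level 10% of its depth below the crista base, with
  sub-sample linear interpolation (bias ~0.5%).
* **Crista base and depth** — the base is the 2nd percentile of the
  non-furrow samples (the ripple valleys); furrow-adjacent samples are
  excluded with 30% padding per side so upper-wall points do not leak into
  the crista statistics. `H` is the mean run depth below this base (bias
  ≈ +0.2·u_h from the percentile, i.e. ~2% for the bundled presets).
* **Ripple estimation** — per crista segment: a periodogram provides a
  first-pass ripple scale u_w⁰; the segment is lightly smoothed (uniform
  window 0.1·u_w⁰); peaks come from `scipy.signal.find_peaks` with 10%
  prominence and a 0.5·u_w⁰ minimum separation; peaks within 0.6·u_w⁰ of
  a segment edge are discarded (truncated bumps at the furrow cliff
  otherwise bias the mean spacing by ~6%). `u_w` is the mean retained-peak
  spacing; `u_h` the mean peak height above the segment-wide minimum
  between the first and last peaks (per-pair minima systematically miss
  the bottom of the steep elliptical joints on a finite grid). Fewer than
  three retained peaks → SMT reported absent.

The elliptical ripple has vertical tangents at its joints, so resolving
the peak-to-valley amplitude to a few percent requires sampling finer than
~1e-3·u_w; the round-trip tests therefore use 12 000 samples per period
(three periods), recovering all five parameters within 2.6% for every
preset (the default tracer resolution recovers them within ~8%).

## Synthetic height maps

`synth_height_map` extrudes the profile along y over a chosen extent
(default mimics a 708 µm × 531 µm laser-microscope field) and adds
independent per-pixel Gaussian height noise, seeded. It emulates the
pixelation, field size and additive measurement noise of real scans, but
not instrument artifacts (tilt, dropouts, speckle, anisotropic ripple or
curvature of real ridges) — passing round-trip tests therefore demonstrate
estimator self-consistency on model-faithful data, not performance on raw
microscope output.

## Empirical closed forms and sweeps

The published linear lobe models (A and 1/σ affine in u_w/u_h with a weak
W_V/W correction), the reflectance/transmittance sigmoids in incidence
angle, and the Spearman methodology are implemented literally, with every
constant in an overridable coefficients table. Angle averages use
composite trapezoid quadrature at 0.01° (reproducing the published
transmittance averages 0.495/0.479 to better than ±0.005). Two documented
caveats:

* The printed reflectance sigmoid is internally inconsistent with the
  reflectance averages quoted alongside it (its angle average is ~0.92 to
  0.96 over the ensemble range, not 0.081–0.094). The form is kept as
  printed; only its monotone increase with u_w/u_h is asserted.
* The transmission width bracket becomes negative near grazing incidence
  (θ ≳ 40–50° for ensemble ratios); evaluation there raises an explicit
  undefined-σ error.

`run_sweep` realizes dimensionless grid points as concrete geometry with
mid-ensemble anchors (u_h = 2 µm, W_V = 40 µm, H = 20 µm; u_w and W follow
from the ratios), traces each point, and Gaussian-fits the lobe. The
package's own re-fitted coefficients are reported alongside the published
ones but are not required to match them numerically (different tracer,
sample geometries not fully published); only signs, linearity and monotone
structure are asserted: on the standard sweep (W_V/W = 0.11, θᵢ = 45°,
u_w/u_h ∈ {12, 15, 19, 25}, 10⁵ rays) the affine fit of 1/σ against
u_w/u_h attains R² ≈ 0.999 with positive slope and Spearman(u, σ) = -1.

## Translucency index

τ_direct = ⟨[1-R(θ)]·T(θ′)⟩ with θ′ = asin(sin θ/n), n fixed at 1.4
(configurable); τ_diffuse = ⟨1-R⟩·⟨T⟩; τ = η·τ_diffuse + (1-η)·τ_direct.
η is an input, never estimated — the model provides no estimator for the
diffuse fraction, and the "complete reflection by the deeper layer" is
treated as lossless direction reversal. Under the printed R and T forms
the computed ordering is τ_direct > τ_diffuse for ensemble ratios (the
opposite of the published qualitative claim); the ordering is therefore
computed and reported but not asserted in either direction. What is
asserted: exact endpoint algebra, affinity in η, and that finer ripple
(smaller u_w/u_h) always yields the higher index.

## Problem sizes and numerical defaults

Simulation-backed results use 10⁵ rays per run (statistical fluctuation of
R below ~2e-3 absolute), 1° bins, power cutoff 1e-4, depth 20. Quadrature
for angle averages is 0.01°; refinement to 0.001° changes τ by < 1e-5.
Unit tests use 2 000–50 000 rays where only structure is asserted.

## Known limitations

* Pure 2D in-plane geometric optics: no out-of-plane scattering,
  polarization-resolved output, wavelength dependence, interference or
  diffraction.
* Single uniform medium: no multilayer transport or absorption, so
  transmission-side results describe the surface crossing only.
* The parameterizer assumes one dominant ripple scale per ridge and a
  shared crista baseline across a section; strongly tilted or multi-scale
  sections need external detrending first.
* The empirical forms are valid only inside the measured ensemble ranges
  (u_w/u_h ≈ 9–39, W_V/W ≈ 0.05–0.58); evaluation outside warns.
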