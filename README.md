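# smtoptics

Light scattering on skin **subvisible micro texture** (SMT): a parametric
surface model, a Monte Carlo ray tracer, and empirical closed-form models
quantifying how micrometer-scale skin topography controls diffuse
reflection (the *soft-focus* effect), diffuse transmission, and a
translucency index.

Skin ridges (crista cutis) carry a ripple of bumps a few micrometers tall
and tens of micrometers wide that is invisible to the naked eye yet
dominates how the skin surface scatters light. This package is for
researchers in tissue optics, cosmetic science and appearance modeling who
want to go from topography parameters (or height-map scans) to quantitative
scattering predictions.

## Model

One macro period of the surface cross section h(x) consists of a furrow
(sulcus cutis) of width `W_V` and depth `H` with quarter-ellipse walls,
and a ridge top carrying half-ellipse bumps of peak-to-valley height `u_h`
and period `u_w`. A 2D tracer splits every ray at the surface into
Fresnel-weighted reflected/refracted children and bins escaping power by
exit angle θₛ. The scattered lobe follows the Gaussian radiance model

    I(θ) = A · exp(−(θ − µ)² / 2σ²)

whose amplitude A and diffuse broadening width σ are governed by the
dimensionless texture descriptors u_w/u_h (ripple aspect ratio) and W_V/W
(furrow fraction): A and 1/σ are affine in u_w/u_h, and the total
reflectance R₁→₁.₄(θᵢ) / transmittance T₁.₄→₁(θᵢ) follow sigmoids in the
incidence angle. The translucency index mixes a direction-preserving and a
diffuse escape channel:

    τ_direct  = ⟨[1 − R(θᵢ)] · T(θᵢ′)⟩,  θᵢ′ = asin(sin θᵢ / 1.4)
    τ_diffuse = ⟨1 − R⟩ · ⟨T⟩
    τ         = η · τ_diffuse + (1 − η) · τ_direct

See `docs/methods.md` for assumptions, estimators and numerical choices.

## Worked example

```python
from smtoptics import (PRESETS, build_profile, simulate_scattering,
                       fit_gaussian, angle_average, T_model, tau_total)

profile = build_profile(PRESETS["sample1"])          # soft-skin preset
res = simulate_scattering(profile, theta_i_deg=45, ray_count=100_000, seed=1)
print(f"R = {res.reflectance:.4f}  T = {res.transmittance:.4f}")
fit = fit_gaussian(res.reflection_distribution)
print(f"sigma = {fit.sigma_deg:.1f} deg  A = {fit.A:.2e}")
print(f"<T>(11.8) = {angle_average(T_model, 11.8):.3f}")
print(f"tau(eta=0.5, u=11.8) = {tau_total(0.5, 11.8).tau:.4f}")
```

prints

```
R = 0.0328  T = 0.9672
sigma = 15.3 deg  A = 7.81e-04
<T>(11.8) = 0.496
tau(eta=0.5, u=11.8) = 0.0507
```

Sample 1 (fine ripple, u_w/u_h ≈ 12) reflects 3.3% of 45°-incident light
into a broad lobe (σ ≈ 15°) — a strong soft-focus surface. The same run on
the rougher sample 2 (u_w/u_h ≈ 25) gives a narrower, brighter lobe
(σ ≈ 6.4°, A ≈ 1.7e-03). `<T>(11.8) = 0.496` is the transmittance of the
empirical model averaged uniformly over incidence angles, and the
translucency index at an even diffuse/direct mix follows from it.

A CLI wraps the same operations:

```sh
smtoptics simulate --preset sample1 --theta 45 --rays 100000 --out runs/
smtoptics sweep --u-ratio 12 --u-ratio 15 --u-ratio 19 --u-ratio 25 --out runs/
smtoptics synth --preset sb6 --noise-sd 0.1 --seed 7 map.csv
smtoptics parameterize map.csv
smtoptics translucency --u-ratio 11.8 --u-ratio 25
```

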