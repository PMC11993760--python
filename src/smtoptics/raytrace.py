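"""2D Monte Carlo forward ray tracing on a periodic height profile.

The tracer launches a fan of parallel rays at a chosen incidence angle onto
a sampled surface profile separating air (above) from a uniform dielectric
medium (below), and follows every ray through successive surface
interactions.  At each hit the ray is split *deterministically* into a
reflected and a refracted child weighted by the unpolarized Fresnel power
coefficients (the refracted child is omitted under total internal
reflection); Monte Carlo randomness enters only through the seeded launch
positions, drawn uniformly over one macro period.  Children are traced until
they escape the surface slab upward or downward, fall below a power cutoff,
or exceed the bounce limit; escaping power is binned by global exit angle.

Two illumination modes cover the two optical observables:

* ``reflection``  — light incident from air; power returned to air is the
  diffuse reflectance R (air -> medium illumination).
* ``transmission`` — light incident from inside the medium; power delivered
  to air is the diffuse transmittance T (medium -> air illumination).

In both modes ``reflectance`` is the power returned to the source-side
medium and ``transmittance`` the power crossing the surface, so the labels
match the physical R and T regardless of mode.  Absorption is zero; the
medium is uniform and subsurface scattering is not modeled.  Scattering is
in-plane (the profile is notionally extruded along the third axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numba import njit

from .geometry import SurfaceProfile
from .scatterfit import AngularDistribution

__all__ = [
    "RayState",
    "Hit",
    "FresnelResult",
    "ScatterResult",
    "fresnel_unpolarized",
    "intersect_height_field",
    "simulate_scattering",
]


class FresnelResult(NamedTuple):
    R: float
    T: float
    refraction_angle_deg: float  # NaN under total internal reflection
    tir: bool


def fresnel_unpolarized(incidence_angle_deg: float, n1: float, n2: float) -> FresnelResult:
    """Unpolarized Fresnel power coefficients and Snell refraction angle.

    ``R`` is the mean of the s- and p-polarized power reflectances and
    ``T = 1 - R``.  Beyond the critical angle (n1 > n2) the result is
    ``R = 1`` with the TIR flag set.
    """
    th = float(incidence_angle_deg)
    if not 0.0 <= th <= 90.0:
        raise ValueError("incidence angle must lie in [0, 90] degrees")
    if n1 < 1 or n2 < 1:
        raise ValueError("refractive indices must be >= 1")
    cosi = math.cos(math.radians(th))
    sini = math.sin(math.radians(th))
    eta = n1 / n2
    k = 1.0 - eta * eta * sini * sini
    if k <= 0.0:
        return FresnelResult(1.0, 0.0, math.nan, True)
    cost = math.sqrt(k)
    rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
    rp = (n1 * cost - n2 * cosi) / (n1 * cost + n2 * cosi)
    R = 0.5 * (rs * rs + rp * rp)
    return FresnelResult(R, 1.0 - R, math.degrees(math.acos(cost)), False)


@dataclass(frozen=True)
class RayState:
    """A ray in the tracing plane: origin (x, z) um, unit direction, power."""

    origin: tuple[float, float]
    direction: tuple[float, float]
    power: float = 1.0
    medium_index: float = 1.0

    def __post_init__(self) -> None:
        dx, dz = self.direction
        norm = math.hypot(dx, dz)
        if norm == 0:
            raise ValueError("ray direction must be non-zero")
        if abs(norm - 1.0) > 1e-12:
            raise ValueError("ray direction must be unit length (|d| - 1 <= 1e-12)")
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power must lie in [0, 1]")


class Hit(NamedTuple):
    point: tuple[float, float]
    normal: tuple[float, float]       # unit, oriented against the ray
    incidence_angle_deg: float


_T_EPS = 1e-6     # um; minimum travel before a new intersection counts
_S_TOL = 1e-12    # tolerance on the segment parameter


@njit(cache=True)
def _march(h1, dxc, P, zmin, zmax, ox, oz, dx, dz, max_steps):
    """First intersection of a ray with the periodic polyline.

    Returns (code, t, i): code 0 = hit on segment i at ray parameter t,
    1 = escaped upward, 2 = escaped downward, 3 = step cap exceeded.
    """
    M = h1.shape[0] - 1
    xm = ox % P
    if xm < 0.0:
        xm += P
    shift = ox - xm  # segment frame offset so segments line up with the ray
    i = int(xm // dxc)
    if i >= M:
        i = M - 1
    if dx == 0.0:
        # vertical ray: only the current cell can be hit
        x1 = i * dxc + shift
        z1 = h1[i]
        ez = h1[i + 1] - z1
        denom = -dz * dxc
        if denom != 0.0:
            t = ((x1 - ox) * ez - (z1 - oz) * dxc) / denom
            if t > _T_EPS:
                s = (ox + t * dx - x1) / dxc
                if -_S_TOL <= s <= 1.0 + _S_TOL:
                    return 0, t, i
        if dz > 0.0:
            return 1, 0.0, -1
        return 2, 0.0, -1
    steps = 0
    while steps < max_steps:
        steps += 1
        x1 = i * dxc + shift
        z1 = h1[i]
        ez = h1[i + 1] - z1
        denom = dx * ez - dz * dxc
        if denom != 0.0:
            t = ((x1 - ox) * ez - (z1 - oz) * dxc) / denom
            if t > _T_EPS:
                s = (ox + t * dx - x1) / dxc
                if -_S_TOL <= s <= 1.0 + _S_TOL:
                    return 0, t, i
        if dx > 0.0:
            xb = x1 + dxc
            i += 1
            if i == M:
                i = 0
                shift += P
        else:
            xb = x1
            i -= 1
            if i < 0:
                i = M - 1
                shift -= P
        tb = (xb - ox) / dx
        if tb > 0.0:
            zb = oz + tb * dz
            if dz > 0.0 and zb > zmax:
                return 1, 0.0, -1
            if dz < 0.0 and zb < zmin:
                return 2, 0.0, -1
    return 3, 0.0, -1


@njit(cache=True)
def _trace_kernel(h1, dxc, P, zmin, zmax, x0, z0, d0x, d0z, start_in_medium,
                  n_out, n_in, max_depth, cutoff_abs, binw, nbins, max_steps):
    """Trace all launched rays; returns histograms and power bookkeeping."""
    hist_up = np.zeros(nbins)
    hist_down = np.zeros(nbins)
    pow_up = 0.0
    pow_down = 0.0
    residual = 0.0
    n_hits = 0
    deepest = 0

    cap = max_depth + 8
    sx = np.empty(cap)
    sz = np.empty(cap)
    sdx = np.empty(cap)
    sdz = np.empty(cap)
    sp = np.empty(cap)
    smed = np.empty(cap, np.int8)
    sdep = np.empty(cap, np.int64)

    w0 = 1.0 / x0.shape[0]
    for r in range(x0.shape[0]):
        top = 0
        sx[0] = x0[r]
        sz[0] = z0
        sdx[0] = d0x
        sdz[0] = d0z
        sp[0] = w0
        smed[0] = start_in_medium
        sdep[0] = 0
        top = 1
        while top > 0:
            top -= 1
            ox = sx[top]
            oz = sz[top]
            dx = sdx[top]
            dz = sdz[top]
            p = sp[top]
            med = smed[top]
            depth = sdep[top]
            if depth > deepest:
                deepest = depth

            code, t, i = _march(h1, dxc, P, zmin, zmax, ox, oz, dx, dz, max_steps)
            if code == 1:
                ang = math.degrees(math.atan2(dx, dz))
                b = int((ang + 90.0) / binw)
                if b < 0:
                    b = 0
                if b >= nbins:
                    b = nbins - 1
                hist_up[b] += p
                pow_up += p
                continue
            if code == 2:
                ang = math.degrees(math.atan2(dx, -dz))
                b = int((ang + 90.0) / binw)
                if b < 0:
                    b = 0
                if b >= nbins:
                    b = nbins - 1
                hist_down[b] += p
                pow_down += p
                continue
            if code == 3:
                residual += p
                continue

            n_hits += 1
            hx = ox + t * dx
            hz = oz + t * dz
            ez = h1[i + 1] - h1[i]
            nlen = math.sqrt(dxc * dxc + ez * ez)
            nx = -ez / nlen
            nz = dxc / nlen
            if dx * nx + dz * nz > 0.0:
                nx = -nx
                nz = -nz
            cosi = -(dx * nx + dz * nz)
            if cosi > 1.0:
                cosi = 1.0
            if med == 1:
                n1 = n_in
                n2 = n_out
            else:
                n1 = n_out
                n2 = n_in
            eta = n1 / n2
            sin2 = 1.0 - cosi * cosi
            if sin2 < 0.0:
                sin2 = 0.0
            k = 1.0 - eta * eta * sin2
            if k <= 0.0:
                refl = 1.0
                cost = 0.0
            else:
                cost = math.sqrt(k)
                rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
                rp = (n1 * cost - n2 * cosi) / (n1 * cost + n2 * cosi)
                refl = 0.5 * (rs * rs + rp * rp)

            # reflected child
            pr = p * refl
            if depth + 1 > max_depth:
                residual += p
                continue
            rdx = dx + 2.0 * cosi * nx
            rdz = dz + 2.0 * cosi * nz
            rn = math.hypot(rdx, rdz)
            rdx /= rn
            rdz /= rn
            if pr >= cutoff_abs:
                if top < cap:
                    sx[top] = hx + _T_EPS * rdx
                    sz[top] = hz + _T_EPS * rdz
                    sdx[top] = rdx
                    sdz[top] = rdz
                    sp[top] = pr
                    smed[top] = med
                    sdep[top] = depth + 1
                    top += 1
                else:
                    residual += pr
            elif pr > 0.0:
                residual += pr

            # refracted child
            if k > 0.0:
                pt = p * (1.0 - refl)
                tdx = eta * dx + (eta * cosi - cost) * nx
                tdz = eta * dz + (eta * cosi - cost) * nz
                tn = math.hypot(tdx, tdz)
                tdx /= tn
                tdz /= tn
                if pt >= cutoff_abs:
                    if top < cap:
                        sx[top] = hx + _T_EPS * tdx
                        sz[top] = hz + _T_EPS * tdz
                        sdx[top] = tdx
                        sdz[top] = tdz
                        sp[top] = pt
                        smed[top] = 1 - med
                        sdep[top] = depth + 1
                        top += 1
                    else:
                        residual += pt
                elif pt > 0.0:
                    residual += pt

    return hist_up, hist_down, pow_up, pow_down, residual, n_hits, deepest


@dataclass(frozen=True)
class ScatterResult:
    """Outcome of one simulated illumination run.

    ``reflectance`` is the power fraction returned to the source-side
    medium, ``transmittance`` the fraction crossing the surface; with
    air-side illumination (mode ``reflection``) these are R(air->medium)
    and with medium-side illumination (mode ``transmission``) the
    transmittance is T(medium->air).  ``residual`` is power terminated by
    the cutoff/bounce limits, never silently dropped.
    """

    reflection_distribution: AngularDistribution
    transmission_distribution: AngularDistribution
    reflectance: float
    transmittance: float
    residual: float
    theta_i_deg: float
    mode: str
    ray_count: int
    seed: int
    n_interactions: int
    max_depth_reached: int

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "theta_i_deg": self.theta_i_deg,
            "reflectance": self.reflectance,
            "transmittance": self.transmittance,
            "residual": self.residual,
            "ray_count": self.ray_count,
            "seed": self.seed,
            "n_interactions": self.n_interactions,
            "max_depth_reached": self.max_depth_reached,
        }


def simulate_scattering(
    profile: SurfaceProfile,
    theta_i_deg: float,
    mode: str = "reflection",
    *,
    n_outside: float = 1.0,
    n_inside: float | None = None,
    ray_count: int = 100_000,
    seed: int = 0,
    max_depth: int = 20,
    power_cutoff: float = 1e-4,
    bin_width_deg: float = 1.0,
    max_march_factor: int = 64,
) -> ScatterResult:
    """Simulate diffuse reflection or transmission on a surface profile.

    Parameters
    ----------
    theta_i_deg : float
        Incidence angle from the global surface normal, 0 <= theta < 90.
    mode : str
        ``"reflection"`` (source in air, above) or ``"transmission"``
        (source inside the medium, below).
    power_cutoff : float
        Fraction of a primary ray's launch power below which a child is
        terminated into the residual.
    """
    if not 0.0 <= theta_i_deg < 90.0:
        raise ValueError("incidence angle must lie in [0, 90) degrees")
    if mode not in ("reflection", "transmission"):
        raise ValueError(f"unknown mode {mode!r}")
    if ray_count < 1:
        raise ValueError("ray_count must be >= 1")
    if n_inside is None:
        n_inside = profile.params.n if profile.params is not None else 1.40
    x1, h1 = profile.one_period()
    if not np.isfinite(h1).all():
        raise ValueError("profile heights must be finite")
    zmin = float(h1.min())
    zmax = float(h1.max())
    P = float(profile.period)
    dxc = float(profile.dx)

    rng = np.random.default_rng(seed)
    x0 = rng.uniform(0.0, P, ray_count)
    th = math.radians(theta_i_deg)
    if mode == "reflection":
        d0x, d0z = math.sin(th), -math.cos(th)
        z0 = zmax + 1.0
        start_in_medium = 0
    else:
        d0x, d0z = math.sin(th), math.cos(th)
        z0 = zmin - 1.0
        start_in_medium = 1

    nbins = int(round(180.0 / bin_width_deg))
    if abs(nbins * bin_width_deg - 180.0) > 1e-9:
        raise ValueError("bin width must divide 180 degrees")
    cutoff_abs = power_cutoff / ray_count
    max_steps = max_march_factor * profile.samples_per_period

    hist_up, hist_down, pow_up, pow_down, residual, n_hits, deepest = _trace_kernel(
        np.ascontiguousarray(h1), dxc, P, zmin, zmax,
        x0, z0, d0x, d0z, start_in_medium,
        float(n_outside), float(n_inside),
        max_depth, cutoff_abs, bin_width_deg, nbins, max_steps,
    )

    centers = -90.0 + (np.arange(nbins) + 0.5) * bin_width_deg
    dist_up = AngularDistribution(
        theta_deg=centers, intensity=hist_up / bin_width_deg,
        total_power=float(hist_up.sum()),
        side="reflection" if mode == "reflection" else "transmission",
    )
    dist_down = AngularDistribution(
        theta_deg=centers, intensity=hist_down / bin_width_deg,
        total_power=float(hist_down.sum()),
        side="transmission" if mode == "reflection" else "reflection",
    )
    if mode == "reflection":
        refl, trans = float(pow_up), float(pow_down)
        refl_dist, trans_dist = dist_up, dist_down
    else:
        refl, trans = float(pow_down), float(pow_up)
        refl_dist, trans_dist = dist_down, dist_up

    return ScatterResult(
        reflection_distribution=refl_dist,
        transmission_distribution=trans_dist,
        reflectance=refl,
        transmittance=trans,
        residual=float(residual),
        theta_i_deg=theta_i_deg,
        mode=mode,
        ray_count=ray_count,
        seed=seed,
        n_interactions=int(n_hits),
        max_depth_reached=int(deepest),
    )


def intersect_height_field(profile: SurfaceProfile, ray: RayState) -> Hit | None:
    """First intersection of a ray with the sampled profile, or None.

    The x coordinate wraps periodically; "no hit" means the ray escapes the
    slab above max(h) or below min(h) without touching the surface.
    """
    x1, h1 = profile.one_period()
    ox, oz = ray.origin
    dx, dz = ray.direction
    code, t, i = _march(
        np.ascontiguousarray(h1), float(profile.dx), float(profile.period),
        float(h1.min()), float(h1.max()), float(ox), float(oz),
        float(dx), float(dz), 64 * profile.samples_per_period,
    )
    if code != 0:
        return None
    hx, hz = ox + t * dx, oz + t * dz
    ez = h1[i + 1] - h1[i]
    nlen = math.hypot(profile.dx, ez)
    nx, nz = -ez / nlen, profile.dx / nlen
    if dx * nx + dz * nz > 0:
        nx, nz = -nx, -nz
    cosi = min(1.0, -(dx * nx + dz * nz))
    return Hit(point=(hx, hz), normal=(nx, nz),
               incidence_angle_deg=math.degrees(math.acos(cosi)))
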