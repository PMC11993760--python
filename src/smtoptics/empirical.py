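"""Empirical closed-form models linking surface texture to scattering.

Parametric ray-tracing sweeps over the dimensionless texture descriptors

* ``u_ratio``  = u_w/u_h  — aspect ratio of the micro ripple (large = smooth),
* ``wv_ratio`` = W_V/W    — furrow width fraction of the macro texture,

collapse onto simple functional families: the Gaussian lobe amplitude ``A``
is affine in ``u_ratio`` (with a weak ``wv_ratio`` correction), the inverse
lobe width ``1/sigma`` is affine in ``u_ratio``, and the total reflectance /
transmittance versus incidence angle follows a sigmoid whose plateau,
steepness and center are themselves simple functions of ``u_ratio``.  This
module evaluates those published forms literally (with every constant
exposed in a coefficients table so suspected misprints can be overridden
without code changes), provides angle averaging, Spearman rank correlation,
and the machinery to re-fit the same functional families to this package's
own simulation sweeps.

The published reflectance sigmoid is known to be internally inconsistent
with the reflectance averages quoted alongside it (the printed form yields
angle averages near 0.93-0.96, not 0.081-0.094); it is kept exactly as
printed and only its monotone structure is relied upon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .geometry import SKIN_INDEX, SurfaceParams, build_profile
from .scatterfit import fit_gaussian
from .raytrace import simulate_scattering

__all__ = [
    "EmpiricalInputs",
    "ReflectionLobeCoeffs",
    "TransmissionLobeCoeffs",
    "SigmoidCoefficients",
    "REFLECTANCE_SIGMOID",
    "TRANSMITTANCE_SIGMOID",
    "A_reflection",
    "sigma_reflection",
    "A_transmission",
    "sigma_transmission",
    "R_model",
    "T_model",
    "angle_average",
    "spearman_rank",
    "run_sweep",
    "fit_affine",
    "fit_linear_form",
    "fit_sigmoid_form",
]

#: Parameter ranges spanned by the measured sample ensemble; the empirical
#: forms are only supported inside them and evaluation outside warns.
U_RATIO_RANGE = (30.0 / 3.2, 58.4 / 1.5)
WV_RATIO_RANGE = (20.0 / 395.5, 60.0 / 103.0)


@dataclass(frozen=True)
class EmpiricalInputs:
    """Dimensionless inputs of the empirical scattering models."""

    u_ratio: float            # u_w / u_h
    wv_ratio: float = 0.11    # W_V / W
    I_s: float = 1.0          # total scattering intensity (normalization)
    theta_i_deg: float = 45.0

    def __post_init__(self) -> None:
        if self.u_ratio <= 0:
            raise ValueError("u_ratio must be > 0")
        if not 0.0 <= self.wv_ratio < 1.0:
            raise ValueError("wv_ratio must lie in [0, 1)")
        if self.I_s <= 0:
            raise ValueError("I_s must be > 0")


def _warn_range(inputs: EmpiricalInputs) -> None:
    if not U_RATIO_RANGE[0] <= inputs.u_ratio <= U_RATIO_RANGE[1]:
        warnings.warn(
            f"u_ratio={inputs.u_ratio:.3g} outside the supported range "
            f"{U_RATIO_RANGE}", stacklevel=3)
    if not WV_RATIO_RANGE[0] <= inputs.wv_ratio <= WV_RATIO_RANGE[1]:
        warnings.warn(
            f"wv_ratio={inputs.wv_ratio:.3g} outside the supported range "
            f"{WV_RATIO_RANGE}", stacklevel=3)


@dataclass(frozen=True)
class ReflectionLobeCoeffs:
    """Constants of the reflection lobe models A(u, wv) and sigma(u, wv):

    A/I_s = (a - b*wv) u - c          1/sigma = (d - e*wv) u - f
    """

    a: float = 0.0023
    b: float = 0.0016
    c: float = 0.00029
    d: float = 0.006
    e: float = 0.0007
    f: float = 0.009


@dataclass(frozen=True)
class TransmissionLobeCoeffs:
    """Constants of the transmission lobe models (theta-dependent):

    A/I_s   = (1 - wv)      [(a cos th - b) u + c (1 - cos th)]
    1/sigma = (1 - g*wv)    [(d cos th - e) u + f (1 - cos th)]
    """

    a: float = 0.028
    b: float = 0.0196
    c: float = 0.0493
    d: float = 0.089
    e: float = 0.0604
    f: float = 0.23
    g: float = 0.71


@dataclass(frozen=True)
class SigmoidCoefficients:
    """Six constants of the reflectance/transmittance sigmoid family.

    plateau(u) = p0 -/+ p1/u, steepness(u) = k0 - k1/u,
    center(u)  = c0 + c1/u; ``complement`` selects the reflectance reading
    (one minus the sigmoid, plateau = p0 + p1/u).
    """

    p0: float
    p1: float
    k0: float
    k1: float
    c0: float
    c1: float
    complement: bool
    mode: str

    def as_array(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.k0, self.k1, self.c0, self.c1])


REFLECTANCE_SIGMOID = SigmoidCoefficients(
    p0=0.00016, p1=0.97, k0=0.11, k1=0.26, c0=87.44, c1=107.15,
    complement=True, mode="reflection",
)
TRANSMITTANCE_SIGMOID = SigmoidCoefficients(
    p0=0.94, p1=0.44, k0=0.32, k1=2.00, c0=44.28, c1=61.57,
    complement=False, mode="transmission",
)


def A_reflection(inputs: EmpiricalInputs, coeffs: ReflectionLobeCoeffs = ReflectionLobeCoeffs()) -> float:
    """Reflection lobe amplitude A = I_s [(a - b Wv/W) u_w/u_h - c]."""
    _warn_range(inputs)
    return inputs.I_s * ((coeffs.a - coeffs.b * inputs.wv_ratio) * inputs.u_ratio - coeffs.c)


def sigma_reflection(inputs: EmpiricalInputs, coeffs: ReflectionLobeCoeffs = ReflectionLobeCoeffs()) -> float:
    """Reflection lobe width sigma = [(d - e Wv/W) u_w/u_h - f]^-1 (degrees)."""
    _warn_range(inputs)
    inv = (coeffs.d - coeffs.e * inputs.wv_ratio) * inputs.u_ratio - coeffs.f
    if inv <= 0:
        raise ValueError(f"sigma undefined: inverse-width bracket {inv:.3g} <= 0")
    return 1.0 / inv


def A_transmission(inputs: EmpiricalInputs, coeffs: TransmissionLobeCoeffs = TransmissionLobeCoeffs()) -> float:
    """Transmission lobe amplitude (depends on the incidence angle)."""
    _warn_range(inputs)
    c = np.cos(np.radians(inputs.theta_i_deg))
    return inputs.I_s * (1.0 - inputs.wv_ratio) * (
        (coeffs.a * c - coeffs.b) * inputs.u_ratio + coeffs.c * (1.0 - c)
    )


def sigma_transmission(inputs: EmpiricalInputs, coeffs: TransmissionLobeCoeffs = TransmissionLobeCoeffs()) -> float:
    """Transmission lobe width (degrees; depends on the incidence angle)."""
    _warn_range(inputs)
    c = np.cos(np.radians(inputs.theta_i_deg))
    inv = (1.0 - coeffs.g * inputs.wv_ratio) * (
        (coeffs.d * c - coeffs.e) * inputs.u_ratio + coeffs.f * (1.0 - c)
    )
    if inv <= 0:
        raise ValueError(f"sigma undefined: inverse-width bracket {inv:.3g} <= 0")
    return 1.0 / inv


def _sigmoid_eval(theta_i_deg, u_ratio, c: SigmoidCoefficients):
    th = np.asarray(theta_i_deg, dtype=float)
    u = float(u_ratio)
    steep = c.k0 - c.k1 / u
    center = c.c0 + c.c1 / u
    if c.complement:
        num = c.p0 + c.p1 / u
        return 1.0 - num / (1.0 + np.exp(steep * (th - center)))
    num = c.p0 - c.p1 / u
    return num / (1.0 + np.exp(steep * (th - center)))


def R_model(theta_i_deg, u_ratio, coeffs: SigmoidCoefficients = REFLECTANCE_SIGMOID):
    """Diffuse reflectance R(air->medium) versus incidence angle (literal form)."""
    th = np.asarray(theta_i_deg, dtype=float)
    if np.any(th < 0) or np.any(th > 90):
        raise ValueError("incidence angle must lie in [0, 90] degrees")
    return _sigmoid_eval(th, u_ratio, coeffs)


def T_model(theta_i_deg, u_ratio, coeffs: SigmoidCoefficients = TRANSMITTANCE_SIGMOID):
    """Diffuse transmittance T(medium->air) versus incidence angle (literal form)."""
    th = np.asarray(theta_i_deg, dtype=float)
    if np.any(th < 0) or np.any(th > 90):
        raise ValueError("incidence angle must lie in [0, 90] degrees")
    return _sigmoid_eval(th, u_ratio, coeffs)


def angle_average(model, u_ratio: float, resolution_deg: float = 0.01) -> float:
    """Unweighted mean of ``model(theta, u_ratio)`` over theta in [0, 90] deg.

    Composite trapezoid quadrature on a uniform grid of step
    ``resolution_deg`` (must be <= 0.1 degrees).
    """
    if resolution_deg > 0.1:
        raise ValueError("resolution must be <= 0.1 degrees")
    n = int(round(90.0 / resolution_deg))
    theta = np.linspace(0.0, 90.0, n + 1)
    vals = np.asarray(model(theta, u_ratio), dtype=float)
    if vals.shape != theta.shape:
        vals = np.broadcast_to(vals, theta.shape)
    return float(np.trapezoid(vals, theta) / 90.0)


def spearman_rank(x, y, *, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    The p-value uses the t-distribution approximation; with ``exact=True``
    (n <= 10) the exact permutation null is used instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1D sequences, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    if exact:
        if len(x) > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        res = stats.permutation_test(
            (x,), lambda xs: stats.spearmanr(xs, y).statistic,
            permutation_type="pairings", n_resamples=np.inf,
        )
        rho = float(stats.spearmanr(x, y).statistic)
        return rho, float(res.pvalue)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _params_for_ratios(
    u_ratio: float, wv_ratio: float, *, u_h: float = 2.0, W_V: float = 40.0,
    H: float = 20.0, n: float = SKIN_INDEX,
) -> SurfaceParams:
    """Concrete lengths realizing dimensionless sweep ratios.

    The ripple height, sulcus width and depth are pinned at mid-ensemble
    values (u_h = 2 um, W_V = 40 um, H = 20 um) and the free lengths follow:
    u_w = u_ratio * u_h, W = W_V / wv_ratio.
    """
    if wv_ratio <= 0:
        return SurfaceParams(W=max(u_ratio * u_h, 1.0), H=0.0, W_V=0.0,
                             u_h=u_h, u_w=u_ratio * u_h, n=n)
    return SurfaceParams(W=W_V / wv_ratio, H=H, W_V=W_V,
                         u_h=u_h, u_w=u_ratio * u_h, n=n)


def run_sweep(
    u_ratios,
    wv_ratios=(0.11,),
    theta_is=(45.0,),
    mode: str = "reflection",
    *,
    ray_count: int = 100_000,
    seed: int = 0,
    n_medium: float = SKIN_INDEX,
    **tracer_kwargs,
) -> pd.DataFrame:
    """Simulate a grid of texture parameters and Gaussian-fit each lobe.

    One row per (u_ratio, wv_ratio, theta_i): the fitted (A, mu, sigma,
    goodness) of the scattered lobe plus the simulated total R or T.  Each
    run gets a distinct deterministic seed derived from ``seed``.
    """
    u_ratios = list(u_ratios)
    if len(set(u_ratios)) < 1:
        raise ValueError("need at least one u_ratio")
    rows = []
    run = 0
    for wv in wv_ratios:
        for u in u_ratios:
            params = _params_for_ratios(u, wv, n=n_medium)
            profile = build_profile(params, n_periods=1)
            for th in theta_is:
                res = simulate_scattering(
                    profile, th, mode=mode, ray_count=ray_count,
                    seed=seed + run, **tracer_kwargs,
                )
                run += 1
                dist = (res.reflection_distribution if mode == "reflection"
                        else res.transmission_distribution)
                fit = fit_gaussian(dist)
                rows.append({
                    "u_ratio": u, "wv_ratio": wv, "theta_i_deg": th,
                    "A": fit.A, "mu_deg": fit.mu_deg,
                    "sigma_deg": fit.sigma_deg, "goodness": fit.goodness,
                    "R_or_T": (res.reflectance if mode == "reflection"
                               else res.transmittance),
                    "mode": mode,
                })
    return pd.DataFrame(rows)


def fit_affine(x, y) -> tuple[float, float, float]:
    """Least-squares affine fit y = slope*x + intercept; returns (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(intercept), float(r2)


def fit_linear_form(records: pd.DataFrame, value: str = "A") -> dict:
    """Re-fit the lobe linear family to sweep records.

    For ``value="A"``: A/I_s = a u - b (wv u) - c; for ``value="sigma"`` the
    same family is fitted to 1/sigma.  Requires at least two distinct
    wv_ratio values (otherwise a and b are not separable) and at least four
    distinct u_ratio values.
    """
    if records["u_ratio"].nunique() < 4:
        raise ValueError("need >= 4 distinct u_ratio values")
    if records["wv_ratio"].nunique() < 2:
        raise ValueError("rank-deficient design: need >= 2 distinct wv_ratio values")
    u = records["u_ratio"].to_numpy(float)
    wv = records["wv_ratio"].to_numpy(float)
    if value == "A":
        y = records["A"].to_numpy(float)
    elif value == "sigma":
        y = 1.0 / records["sigma_deg"].to_numpy(float)
    else:
        raise ValueError("value must be 'A' or 'sigma'")
    X = np.column_stack([u, wv * u, np.ones_like(u)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum((y - pred) ** 2) / ss_tot if ss_tot > 0 else 0.0
    return {"a": float(beta[0]), "b": float(-beta[1]), "c": float(-beta[2]),
            "r_squared": float(r2)}


def fit_sigmoid_form(records: pd.DataFrame, mode: str = "transmission") -> SigmoidCoefficients:
    """Re-fit the six-constant sigmoid family to sweep (theta_i, u, R/T) records."""
    if records["u_ratio"].nunique() < 4:
        raise ValueError("need >= 4 distinct u_ratio values")
    th = records["theta_i_deg"].to_numpy(float)
    u = records["u_ratio"].to_numpy(float)
    y = records["R_or_T"].to_numpy(float)
    complement = mode == "reflection"

    def family(x, p0, p1, k0, k1, c0, c1):
        tt, uu = x
        num = p0 + p1 / uu if complement else p0 - p1 / uu
        s = num / (1.0 + np.exp((k0 - k1 / uu) * (tt - (c0 + c1 / uu))))
        return 1.0 - s if complement else s

    if complement:
        p0_guess = [0.01, 1.0, 0.1, 0.3, 85.0, 100.0]
    else:
        p0_guess = [float(np.clip(y.max(), 0.1, 1.0)), 0.5, 0.3, 2.0, 45.0, 60.0]
    popt, _ = curve_fit(family, (th, u), y, p0=p0_guess, maxfev=50000)
    return SigmoidCoefficients(*[float(v) for v in popt],
                               complement=complement, mode=mode)
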