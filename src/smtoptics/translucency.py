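"""Translucency index: how much internally reflected light escapes the skin.

Isotropic light inside the skin (refractive index 1.4 by default) that has
been turned around by deeper layers reaches the textured surface and
partially escapes.  Two escape channels are combined:

* ``tau_direct`` — the internally reflected beam keeps its direction, so
  entry and exit angles are Snell-linked: the mean over incidence angles of
  [1 - R(theta)] * T(theta'), with theta' = asin(sin theta / n).
* ``tau_diffuse`` — internal scattering decorrelates entry and exit, so the
  two angle averages factorize: <1 - R> * <T>.

The total index is the mix tau = eta * tau_diffuse + (1 - eta) * tau_direct,
where eta, the diffuse fraction of the internally reflected energy, is an
input (no estimator for it is provided by the model).  R and T are the
empirical sigmoid models by default but can be replaced by any callables
``f(theta_deg, u_ratio)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .empirical import R_model, T_model, angle_average

__all__ = ["TranslucencyResult", "tau_direct", "tau_diffuse", "tau_total"]


@dataclass(frozen=True)
class TranslucencyResult:
    """Direct, diffuse and mixed translucency indices for one texture."""

    tau_direct: float
    tau_diffuse: float
    tau: float
    eta: float
    u_ratio: float
    resolution_deg: float

    def __post_init__(self) -> None:
        expected = self.eta * self.tau_diffuse + (1.0 - self.eta) * self.tau_direct
        if abs(self.tau - expected) > 1e-12:
            raise ValueError("tau is not the stated mix of its components")


def tau_direct(
    u_ratio: float,
    resolution_deg: float = 0.01,
    *,
    n_medium: float = 1.4,
    R=R_model,
    T=T_model,
) -> float:
    """Direction-preserving escape: <[1 - R(theta)] T(theta')> over [0, 90] deg.

    theta' = asin(sin(theta) / n_medium) is the refraction angle of the
    original entry into the medium; at grazing entry it saturates at the
    critical angle asin(1/n).
    """
    if u_ratio <= 0:
        raise ValueError("u_ratio must be > 0")
    if resolution_deg > 0.1:
        raise ValueError("resolution must be <= 0.1 degrees")
    n = int(round(90.0 / resolution_deg))
    theta = np.linspace(0.0, 90.0, n + 1)
    theta_p = np.degrees(np.arcsin(np.sin(np.radians(theta)) / n_medium))
    vals = (1.0 - np.asarray(R(theta, u_ratio), dtype=float)) * \
        np.asarray(T(theta_p, u_ratio), dtype=float)
    return float(np.trapezoid(vals, theta) / 90.0)


def tau_diffuse(
    u_ratio: float,
    resolution_deg: float = 0.01,
    *,
    R=R_model,
    T=T_model,
) -> float:
    """Decorrelated escape: <1 - R> * <T>, both averaged over [0, 90] deg."""
    if u_ratio <= 0:
        raise ValueError("u_ratio must be > 0")
    avg_not_R = 1.0 - angle_average(R, u_ratio, resolution_deg)
    avg_T = angle_average(T, u_ratio, resolution_deg)
    return float(avg_not_R * avg_T)


def tau_total(
    eta: float,
    u_ratio: float,
    resolution_deg: float = 0.01,
    *,
    n_medium: float = 1.4,
    R=R_model,
    T=T_model,
) -> TranslucencyResult:
    """Total translucency index tau = eta*tau_diffuse + (1-eta)*tau_direct."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    td = tau_direct(u_ratio, resolution_deg, n_medium=n_medium, R=R, T=T)
    tf = tau_diffuse(u_ratio, resolution_deg, R=R, T=T)
    return TranslucencyResult(
        tau_direct=td, tau_diffuse=tf,
        tau=eta * tf + (1.0 - eta) * td,
        eta=eta, u_ratio=u_ratio, resolution_deg=resolution_deg,
    )
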