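"""Angular scattering distributions and Gaussian lobe fitting.

Scattered power leaving a rough surface is summarized by a binned angular
distribution I(theta_s) over the exit hemisphere (theta_s in [-90, 90]
degrees, measured from the mean surface normal, signed by the horizontal
direction of travel), and characterized by the Gaussian radiance model

    I(theta) = A * exp(-(theta - mu)^2 / (2 sigma^2)),

whose peak intensity ``A``, center ``mu`` and diffuse broadening width
``sigma`` quantify the strength and angular spread of the scattering lobe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "AngularDistribution",
    "GaussianFitResult",
    "DegenerateFitError",
    "bin_exit_rays",
    "fit_gaussian",
]


class DegenerateFitError(ValueError):
    """Raised when an angular distribution cannot support a Gaussian fit."""


@dataclass(frozen=True)
class AngularDistribution:
    """Binned outgoing power per degree versus scattering angle.

    ``intensity`` is power per degree in each bin, so
    ``sum(intensity) * bin_width == total_power``.
    """

    theta_deg: np.ndarray   # bin centers
    intensity: np.ndarray   # power per degree
    total_power: float
    side: str               # "reflection" | "transmission"

    def __post_init__(self) -> None:
        if self.theta_deg.shape != self.intensity.shape:
            raise ValueError("theta_deg and intensity must have the same shape")
        if len(self.theta_deg) > 1:
            widths = np.diff(self.theta_deg)
            if not np.allclose(widths, widths[0], rtol=1e-9, atol=1e-12):
                raise ValueError("bin widths must be uniform")
        if (self.intensity < 0).any():
            raise ValueError("intensity must be >= 0")
        if abs(self.intensity.sum() * self.bin_width - self.total_power) > 1e-9:
            raise ValueError("binned power does not integrate to total_power")

    @property
    def bin_width(self) -> float:
        if len(self.theta_deg) > 1:
            return float(self.theta_deg[1] - self.theta_deg[0])
        return 180.0 / max(len(self.theta_deg), 1)

    def to_csv(self, path) -> None:
        np.savetxt(
            path, np.column_stack([self.theta_deg, self.intensity]),
            delimiter=",", header="theta_deg,power_per_degree", comments="",
        )


def bin_exit_rays(
    angles_deg,
    powers,
    bin_width_deg: float = 1.0,
    side: str = "reflection",
) -> AngularDistribution:
    """Conservatively bin (exit angle, power) records over [-90, 90] degrees.

    Total power is preserved exactly: every record lands in exactly one bin
    (the +90 edge is folded into the last bin).
    """
    angles = np.asarray(angles_deg, dtype=float)
    powers = np.asarray(powers, dtype=float)
    if angles.shape != powers.shape:
        raise ValueError("angles and powers must have the same shape")
    if (np.abs(angles) > 90).any():
        raise ValueError("angles must lie in [-90, 90] degrees")
    if (powers < 0).any():
        raise ValueError("powers must be >= 0")
    nbins = int(round(180.0 / bin_width_deg))
    if abs(nbins * bin_width_deg - 180.0) > 1e-9 or nbins < 1:
        raise ValueError("bin width must divide 180 degrees")
    idx = np.clip(((angles + 90.0) / bin_width_deg).astype(int), 0, nbins - 1)
    hist = np.zeros(nbins)
    np.add.at(hist, idx, powers)
    centers = -90.0 + (np.arange(nbins) + 0.5) * bin_width_deg
    return AngularDistribution(
        theta_deg=centers, intensity=hist / bin_width_deg,
        total_power=float(hist.sum() * 1.0), side=side,
    )


@dataclass(frozen=True)
class GaussianFitResult:
    """Converged parameters of the Gaussian radiance model."""

    A: float
    mu_deg: float
    sigma_deg: float
    goodness: float  # coefficient of determination, <= 1

    def to_json(self) -> str:
        return json.dumps({
            "A": self.A, "mu_deg": self.mu_deg,
            "sigma_deg": self.sigma_deg, "goodness": self.goodness,
        })


def _gauss(theta, a, mu, sigma):
    return a * np.exp(-((theta - mu) ** 2) / (2.0 * sigma ** 2))


def fit_gaussian(
    dist: AngularDistribution,
    fix_center: float | None = None,
    exclude_spike: bool = False,
) -> GaussianFitResult:
    """Nonlinear least squares of the Gaussian radiance model to a lobe.

    Initialization: A0 = max intensity, mu0 = argmax bin (or ``fix_center``),
    sigma0 = intensity-weighted standard deviation of the bin angles.  All
    bins, including empty ones, enter the (unweighted) loss — empty bins
    constrain sigma.  With ``exclude_spike`` a single bin more than 100x its
    neighbors (an unscattered specular remnant) is dropped before fitting.
    """
    theta = np.asarray(dist.theta_deg, dtype=float)
    inten = np.asarray(dist.intensity, dtype=float)

    if exclude_spike and len(inten) >= 3:
        k = int(np.argmax(inten))
        neighbors = [inten[j] for j in (k - 1, k + 1) if 0 <= j < len(inten)]
        if neighbors and inten[k] > 100.0 * max(max(neighbors), 1e-300):
            keep = np.ones(len(inten), dtype=bool)
            keep[k] = False
            theta, inten = theta[keep], inten[keep]

    nonzero = int((inten > 0).sum())
    if nonzero < 5:
        raise DegenerateFitError(
            f"need >= 5 nonzero bins for a Gaussian fit, got {nonzero}"
        )

    a0 = float(inten.max())
    mu0 = float(theta[np.argmax(inten)]) if fix_center is None else float(fix_center)
    w = inten / inten.sum()
    sigma0 = float(np.sqrt(np.sum(w * (theta - mu0) ** 2)))
    sigma0 = max(sigma0, dist.bin_width / 2.0)

    try:
        if fix_center is None:
            popt, _ = curve_fit(
                _gauss, theta, inten, p0=[a0, mu0, sigma0],
                method="lm", maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            a, mu, sig = popt
        else:
            popt, _ = curve_fit(
                lambda th, a, s: _gauss(th, a, mu0, s), theta, inten,
                p0=[a0, sigma0],
                method="lm", maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            a, sig = popt
            mu = mu0
    except RuntimeError:
        # no convergence (e.g. near-uniform data): report the initial guess
        # with its (poor) goodness rather than failing
        a, mu, sig = a0, mu0, sigma0

    sig = abs(float(sig))
    if sig == 0:
        raise DegenerateFitError("fit collapsed to zero width (single-bin spike)")
    resid = inten - _gauss(theta, a, mu, sig)
    ss_tot = float(np.sum((inten - inten.mean()) ** 2))
    goodness = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return GaussianFitResult(A=float(a), mu_deg=float(mu),
                             sigma_deg=sig, goodness=goodness)
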