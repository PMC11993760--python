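"""Parametric skin-surface geometry.

Facial skin topography is modeled at two scales: a periodic *macro texture*
of furrows (sulcus cutis) separating flat-topped ridges (crista cutis), and a
*subvisible micro texture* (SMT) — a train of micrometer-scale elliptical
bumps riding on the ridge tops.  One macro period of width ``W`` consists of

* a sulcus of width ``W_V`` and depth ``H`` whose two walls are quarter
  ellipses (vertical semi-axis ``H``, horizontal semi-axis ``W_V/2``) meeting
  smoothly at the bottom, and
* a crista top of width ``W - W_V`` at the reference height ``h = 0``
  carrying repeated upper-half-ellipse bumps of peak-to-valley height ``u_h``
  and base period ``u_w``; the bump train starts at the sulcus edge and the
  last bump may be truncated at the far edge of the period.

Heights are in micrometers, ``x`` increases rightward, ``h`` upward; air is
above the surface and the medium (skin or PMMA, refractive index ``n``)
below.  This module builds profiles from parameters, recovers parameters
from measured or synthetic cross sections, and generates synthetic
height-map fixtures emulating laser-microscope scans.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

SKIN_INDEX = 1.40
PMMA_INDEX = 1.49

__all__ = [
    "SKIN_INDEX",
    "PMMA_INDEX",
    "SurfaceParams",
    "SurfaceProfile",
    "HeightMap",
    "ParameterEstimate",
    "PRESETS",
    "REPORTED_U_RATIOS",
    "build_profile",
    "parameterize_profile",
    "synth_height_map",
    "save_height_map",
    "load_height_map",
]


@dataclass(frozen=True)
class SurfaceParams:
    """Five-parameter surface description plus the refractive index.

    Parameters
    ----------
    W : float
        Macro spatial period of the furrow/ridge pattern (um).
    H : float
        Sulcus (furrow) depth below the crista reference plane (um).
    W_V : float
        Sulcus width (um); must satisfy ``W_V < W``.
    u_h : float
        SMT ripple height, peak to valley (um).
    u_w : float
        SMT ripple period (um); when ripple is present it must fit on the
        crista top, ``u_w <= W - W_V``.
    n : float
        Refractive index of the medium below the surface (skin 1.40,
        PMMA 1.49).
    """

    W: float
    H: float
    W_V: float
    u_h: float
    u_w: float
    n: float = SKIN_INDEX

    def __post_init__(self) -> None:
        for name in ("W", "H", "W_V", "u_h", "u_w"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.W <= 0:
            raise ValueError("W must be > 0")
        if self.W_V >= self.W:
            raise ValueError(f"W_V ({self.W_V}) must be < W ({self.W})")
        if self.u_h > 0 and self.u_w <= 0:
            raise ValueError("u_w must be > 0 when u_h > 0 (undefined ripple)")
        if self.u_h > 0 and self.u_w > self.W - self.W_V:
            raise ValueError(
                f"u_w ({self.u_w}) must be <= W - W_V ({self.W - self.W_V})"
            )
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def u_ratio(self) -> float:
        """SMT aspect ratio u_w/u_h (dimensionless)."""
        if self.u_h == 0:
            raise ZeroDivisionError("u_ratio undefined for u_h = 0")
        return self.u_w / self.u_h

    @property
    def wv_ratio(self) -> float:
        """Macro texture ratio W_V/W (dimensionless)."""
        return self.W_V / self.W

    def scaled(self, c: float) -> "SurfaceParams":
        """All five lengths multiplied by ``c`` (refractive index unchanged)."""
        return replace(
            self, W=c * self.W, H=c * self.H, W_V=c * self.W_V,
            u_h=c * self.u_h, u_w=c * self.u_w,
        )


#: Published parameter sets: four facial skin replica samples and two PMMA
#: texture-standard plates (SB6 sandblasted, HD6 molded) used for
#: benchmarking.  The HD6 row of the published table admits two readings of
#: its ripple parameters; both are provided and neither is treated as
#: canonical.
PRESETS: dict[str, SurfaceParams] = {
    "sample1": SurfaceParams(W=288.2, H=29.7, W_V=40.0, u_h=2.7, u_w=32.5, n=SKIN_INDEX),
    "sample2": SurfaceParams(W=240.8, H=17.9, W_V=40.0, u_h=2.1, u_w=53.4, n=SKIN_INDEX),
    "sample3": SurfaceParams(W=286.6, H=18.1, W_V=40.0, u_h=2.0, u_w=30.7, n=SKIN_INDEX),
    "sample4": SurfaceParams(W=264.3, H=26.0, W_V=40.0, u_h=2.7, u_w=58.4, n=SKIN_INDEX),
    "sb6": SurfaceParams(W=200.0, H=20.0, W_V=20.0, u_h=2.0, u_w=20.0, n=PMMA_INDEX),
    "hd6_narrow": SurfaceParams(W=256.4, H=0.0, W_V=0.0, u_h=18.85, u_w=256.4, n=PMMA_INDEX),
    "hd6_wide": SurfaceParams(W=5256.4, H=0.0, W_V=0.0, u_h=18.8, u_w=5256.4, n=PMMA_INDEX),
}

#: The u_w/u_h values quoted in running text for the four skin samples.
#: They do not all agree with the Table quotients (`SurfaceParams.u_ratio`);
#: both sets are exposed without reconciliation.
REPORTED_U_RATIOS: tuple[float, ...] = (15.2, 21.9, 11.8, 25.0)


def _height_one_period(x: np.ndarray, p: SurfaceParams) -> np.ndarray:
    """Analytic height h(x) for x in [0, W) of a single macro period."""
    x = np.asarray(x, dtype=float)
    h = np.zeros_like(x)
    if p.H > 0 and p.W_V > 0:
        in_sulcus = x < p.W_V
        t = (x[in_sulcus] - p.W_V / 2.0) / (p.W_V / 2.0)
        h[in_sulcus] = -p.H * np.sqrt(np.clip(1.0 - t * t, 0.0, None))
    if p.u_h > 0:
        crista = x >= p.W_V
        s = np.mod(x[crista] - p.W_V, p.u_w) / p.u_w
        h[crista] = p.u_h * np.sqrt(np.clip(4.0 * s * (1.0 - s), 0.0, None))
    return h


@dataclass(frozen=True)
class SurfaceProfile:
    """A periodic, piecewise-analytic 1D height profile, sampled for tracing.

    ``x``/``h`` hold the uniform sample grid over ``n_periods`` macro periods
    (open-ended: the point at ``n_periods * period`` is not repeated).
    ``height`` and ``normal`` evaluate the periodic polyline anywhere.
    """

    period: float
    x: np.ndarray
    h: np.ndarray
    n_periods: int
    samples_per_period: int
    params: SurfaceParams | None = None

    @property
    def dx(self) -> float:
        return self.period / self.samples_per_period

    def one_period(self) -> tuple[np.ndarray, np.ndarray]:
        """Closed sample arrays over [0, period] with h[-1] == h[0]."""
        m = self.samples_per_period
        x1 = np.append(self.x[: m], self.period)
        h1 = np.append(self.h[: m], self.h[0])
        return x1, h1

    def height(self, x) -> np.ndarray:
        x1, h1 = self.one_period()
        xm = np.mod(np.asarray(x, dtype=float), self.period)
        return np.interp(xm, x1, h1)

    def normal(self, x) -> np.ndarray:
        """Outward (upward) unit normal of the polyline segment under ``x``.

        Returns an array of shape (..., 2).
        """
        _, h1 = self.one_period()
        xm = np.mod(np.asarray(x, dtype=float), self.period)
        i = np.clip((xm // self.dx).astype(int), 0, self.samples_per_period - 1)
        ez = h1[i + 1] - h1[i]
        ex = np.full_like(ez, self.dx)
        norm = np.hypot(ex, ez)
        return np.stack([-ez / norm, ex / norm], axis=-1)

    def to_csv(self, path) -> None:
        """Two-column export ``x_um,h_um`` of the sample grid."""
        arr = np.column_stack([self.x, self.h])
        np.savetxt(path, arr, delimiter=",", header="x_um,h_um", comments="")


def build_profile(
    params: SurfaceParams,
    n_periods: int = 1,
    samples_per_period: int | None = None,
) -> SurfaceProfile:
    """Sample the analytic two-scale surface onto a uniform grid.

    ``samples_per_period`` defaults to a resolution giving at least 40
    samples per ripple period and at least 1000 samples per macro period.
    The spec floor of 20 samples per ``u_w`` is enforced.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    if samples_per_period is None:
        m = 1000
        if params.u_h > 0:
            m = max(m, int(np.ceil(40.0 * params.W / params.u_w)))
        samples_per_period = m
    if params.u_h > 0 and samples_per_period * params.u_w / params.W < 20:
        raise ValueError(
            "samples_per_period too coarse: u_w must span >= 20 samples"
        )
    dx = params.W / samples_per_period
    x1 = np.arange(samples_per_period) * dx
    h1 = _height_one_period(x1, params)
    x = np.concatenate([x1 + k * params.W for k in range(n_periods)])
    h = np.tile(h1, n_periods)
    return SurfaceProfile(
        period=params.W, x=x, h=h, n_periods=n_periods,
        samples_per_period=samples_per_period, params=params,
    )


@dataclass(frozen=True)
class ParameterEstimate:
    """Parameters recovered from a cross section; absent values are None.

    Macro parameters (W, H, W_V) are absent when no sulcus is detected; SMT
    parameters (u_h, u_w) are absent when fewer than three ripple extrema are
    found.
    """

    W: float | None = None
    H: float | None = None
    W_V: float | None = None
    u_h: float | None = None
    u_w: float | None = None
    n_sulci: int = 0
    n_smt_peaks: int = 0

    @property
    def has_macro(self) -> bool:
        return self.H is not None

    @property
    def has_smt(self) -> bool:
        return self.u_h is not None

    def to_params(self, n: float = SKIN_INDEX) -> SurfaceParams:
        if None in (self.W, self.H, self.W_V, self.u_h, self.u_w):
            raise ValueError("estimate incomplete; cannot build SurfaceParams")
        return SurfaceParams(W=self.W, H=self.H, W_V=self.W_V,
                             u_h=self.u_h, u_w=self.u_w, n=n)


def _dominant_period(seg: np.ndarray, dx: float) -> float | None:
    """First-pass ripple period estimate from the periodogram of a segment."""
    y = seg - seg.mean()
    nfft = max(len(y), 4096)
    spec = np.abs(np.fft.rfft(y, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=dx)
    # exclude DC / macro-scale drift (wavelength > half the segment) and
    # wavelengths under 4 samples
    lo = 2.0 / (len(y) * dx)
    hi = 1.0 / (4.0 * dx)
    ok = (freqs > lo) & (freqs < hi)
    if not ok.any() or spec[ok].max() == 0:
        return None
    return 1.0 / freqs[ok][np.argmax(spec[ok])]


def _smt_from_segments(
    segments: list[np.ndarray], dx: float, prominence_frac: float
) -> tuple[float | None, float | None, int]:
    """Estimate (u_h, u_w, n_peaks) from crista-top cross-section segments.

    Two-pass: a periodogram gives the ripple scale, which sets a light
    smoothing window, a minimum peak separation, and an edge-exclusion margin
    (truncated bumps at segment edges otherwise bias the mean spacing).
    """
    periods = [p for s in segments if len(s) >= 16
               for p in [_dominant_period(s, dx)] if p is not None]
    if not periods:
        return None, None, 0
    uw0 = float(np.median(periods))
    win = max(1, int(round(0.1 * uw0 / dx)))
    min_dist = max(1, int(round(0.5 * uw0 / dx)))
    margin = 0.6 * uw0

    spacings: list[float] = []
    amplitudes: list[float] = []
    n_peaks = 0
    for seg in segments:
        if len(seg) < 8:
            continue
        smooth = uniform_filter1d(seg, size=win, mode="nearest") if win > 1 else seg
        amp = np.percentile(smooth, 99) - np.percentile(smooth, 1)
        if amp <= 0:
            continue
        peaks, _ = signal.find_peaks(
            smooth, prominence=prominence_frac * amp, distance=min_dist
        )
        xs = peaks * dx
        keep = (xs >= margin) & (xs <= (len(seg) - 1) * dx - margin)
        peaks = peaks[keep]
        n_peaks += len(peaks)
        if len(peaks) >= 2:
            spacings.extend(np.diff(peaks) * dx)
            # valley reference: the segment-wide minimum between the first
            # and last retained peaks (per-pair minima systematically miss
            # the bottom of steep-walled valleys on a finite grid)
            valley = seg[peaks[0]:peaks[-1] + 1].min()
            amplitudes.extend(seg[peaks] - valley)
    if n_peaks < 3 or not spacings:
        return None, None, n_peaks
    return float(np.mean(amplitudes)), float(np.mean(spacings)), n_peaks


def parameterize_profile(
    heights,
    spacing: float,
    *,
    sulcus_threshold: float = 0.5,
    wall_fraction: float = 0.1,
    min_depth_ratio: float = 5.0,
    smt_prominence: float = 0.1,
) -> ParameterEstimate:
    """Recover surface parameters from a uniformly sampled cross section.

    Sulci are detected as contiguous runs deeper than ``sulcus_threshold``
    of the robust (1st-99th percentile) height range, then accepted only if
    their mean depth exceeds ``min_depth_ratio`` times the robust amplitude
    of the remaining (crista) signal — the rule separating true furrows
    (depth many times the ripple amplitude) from ripple valleys (depth of
    the same order).  Each accepted run's extent is refined at a crossing
    level ``wall_fraction`` of its depth below the crista base (linear
    interpolation), which removes the elliptical-wall bias of a deep-level
    run length.  ``W`` is the mean spacing of sulcus centers, ``W_V`` the
    mean refined run width, ``H`` the mean run depth below the crista base
    (a low quantile of the non-sulcus heights).  SMT parameters come from
    ripple peaks on the crista segments (see ``_smt_from_segments``).
    """
    h = np.asarray(heights, dtype=float)
    if h.ndim == 2 and h.shape[1] == 2:  # (x, h) pairs
        h = h[:, 1]
    if h.ndim != 1:
        raise ValueError("heights must be a 1D sequence or (x, h) pairs")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if not np.isfinite(h).all():
        raise ValueError("heights must be finite")

    hi, lo = np.percentile(h, [99, 1])
    rng = hi - lo
    if rng <= 1e-12 * max(1.0, abs(hi)):
        return ParameterEstimate()  # flat input: nothing to estimate

    deep = h < hi - sulcus_threshold * rng
    # contiguous runs of deep samples
    edges = np.flatnonzero(np.diff(np.concatenate([[0], deep.view(np.int8), [0]])))
    runs = [(a, b) for a, b in zip(edges[::2], edges[1::2]) if b - a >= 3]

    # exclude a margin around each run so upper-wall samples do not leak
    # into the crista statistics (a run at the 50% level spans only ~85-90%
    # of the groove; 30% padding per side covers the remaining wall)
    crista_mask = np.ones_like(h, dtype=bool)
    for a, b in runs:
        pad = max(3, int(round(0.3 * (b - a))))
        crista_mask[max(0, a - pad):min(len(h), b + pad)] = False
    crista = h[crista_mask]
    macro_ok = False
    if runs and crista.size > 10:
        c_hi, c_lo = np.percentile(crista, [99, 1])
        depths = np.array([hi - h[a:b].min() for a, b in runs])
        macro_ok = depths.mean() > min_depth_ratio * max(c_hi - c_lo, 1e-12)

    W = H = W_V = None
    n_sulci = 0
    smt_segments: list[np.ndarray]
    if macro_ok:
        base = float(np.percentile(crista, 2))  # crista reference (ripple valleys)
        widths, depths_out, centers = [], [], []
        bounds: list[tuple[float, float]] = []
        for a, b in runs:
            d = base - h[a:b].min()
            if d <= 0:
                continue
            level = base - wall_fraction * d
            # walk outward from the run to the crossing of `level`
            left = a
            while left > 0 and h[left - 1] < level:
                left -= 1
            right = b - 1
            while right < len(h) - 1 and h[right + 1] < level:
                right += 1
            # sub-sample crossing positions by linear interpolation
            xl = float(left)
            if left > 0 and h[left - 1] != h[left]:
                xl = left - (level - h[left]) / (h[left - 1] - h[left])
            xr = float(right)
            if right < len(h) - 1 and h[right + 1] != h[right]:
                xr = right + (level - h[right]) / (h[right + 1] - h[right])
            widths.append((xr - xl) * spacing)
            depths_out.append(d)
            centers.append(0.5 * (xl + xr) * spacing)
            bounds.append((xl, xr))
        if widths:
            n_sulci = len(widths)
            H = float(np.mean(depths_out))
            W_V = float(np.mean(widths))
            if len(centers) >= 2:
                W = float(np.mean(np.diff(sorted(centers))))
        # crista segments between refined sulcus extents
        cuts = [0.0] + [e for bnd in bounds for e in bnd] + [float(len(h) - 1)]
        cuts = sorted(cuts)
        smt_segments = []
        for s, e in zip(cuts[::2], cuts[1::2]):
            i0, i1 = int(np.ceil(s)), int(np.floor(e))
            if i1 - i0 >= 8:
                smt_segments.append(h[i0:i1 + 1])
    else:
        smt_segments = [h]

    u_h, u_w, n_peaks = _smt_from_segments(smt_segments, spacing, smt_prominence)
    return ParameterEstimate(W=W, H=H, W_V=W_V, u_h=u_h, u_w=u_w,
                             n_sulci=n_sulci, n_smt_peaks=n_peaks)


@dataclass(frozen=True)
class HeightMap:
    """Gridded surface heights (um) on a regular (x, y) lattice."""

    data: np.ndarray  # shape (ny, nx), um
    spacing: float    # um per pixel, both axes

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.data.ndim != 2:
            raise ValueError("height map must be 2D")
        if not np.isfinite(self.data).all():
            raise ValueError("height map must be finite")

    def row(self, index: int | None = None) -> np.ndarray:
        """A single cross section (central row by default)."""
        i = self.data.shape[0] // 2 if index is None else index
        return self.data[i]


def synth_height_map(
    params: SurfaceParams,
    extent: tuple[float, float],
    spacing: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> HeightMap:
    """Synthetic laser-scan emulation: the profile extruded along y + noise.

    ``extent`` is (x-size, y-size) in um and must span at least one macro
    period in x.  Gaussian height noise of standard deviation ``noise_sd``
    (um) is added independently per pixel; results are reproducible for a
    given ``seed``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    lx, ly = extent
    if lx < params.W:
        raise ValueError("extent must span at least one macro period in x")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    nx = max(2, int(round(lx / spacing)))
    ny = max(1, int(round(ly / spacing)))
    x = np.arange(nx) * spacing
    row = _height_one_period(np.mod(x, params.W), params)
    data = np.tile(row, (ny, 1))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return HeightMap(data=data, spacing=spacing)


def save_height_map(hm: HeightMap, path) -> None:
    """Write a height map as CSV (``# spacing_um=...`` header) or TIFF."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(
            path, hm.data.astype(np.float32),
            description=json.dumps({"spacing_um": hm.spacing}),
        )
    else:
        with open(path, "w", newline="") as fh:
            fh.write(f"# spacing_um={hm.spacing!r}\n")
            writer = csv.writer(fh)
            for r in hm.data:
                writer.writerow([repr(float(v)) for v in r])


def load_height_map(path) -> HeightMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            data = tf.asarray().astype(float)
            desc = tf.pages[0].description
        spacing = float(json.loads(desc)["spacing_um"])
        return HeightMap(data=data, spacing=spacing)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# spacing_um="):
            raise ValueError("missing '# spacing_um=' header in height-map CSV")
        spacing = float(header.split("=", 1)[1])
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return HeightMap(data=data, spacing=spacing)
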