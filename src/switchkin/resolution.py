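"""Resolution calculus: photon-limited precision, Nyquist density limit,
and the thiolate concentration bandpass.

Two independent limits govern achievable SMLM resolution:

* **Photon-limited**: the localization-precision variance for a Gaussian
  PSF of width σ on a camera with pixel size a and background variance b²,

      Δx² = (σ_a²/N) · (16/9 + 8π σ_a² b² / (N a²)),   σ_a² = σ² + a²/12,

  with N detected photons.  For an EMCCD the precision is √(2·Δx²)
  (excess-noise doubling of the variance), and FWHM resolution is
  2.355 × precision.  More thiolate quenches brightness, so this acts as
  a concentration *low-pass* filter.

* **Nyquist-limited**: a label density of n µm⁻² supports a structural
  resolution R = 2/√n.  The τ_off/τ_on ratio bounds the tolerable density
  within a diffraction-limited region (DLR), so this acts as a
  concentration *long-pass* filter (the ratio rises with thiolate).

Normalising the reciprocal resolutions to their own maxima gives two gain
curves whose product — the combined gain — is a bandpass in thiolate
concentration; its crossings at a given level (1/√2 ≈ 70.7 % and 90 % by
default) are the usable concentration band edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, curve_fit

__all__ = [
    "PrecisionParams",
    "DensityModel",
    "ResolutionProfile",
    "localization_resolution",
    "nyquist_resolution",
    "density_capacity",
    "spots_per_fwhm_dlr",
    "gain_curves",
    "bandpass_edges",
]

FWHM_FACTOR = 2.355


@dataclass(frozen=True)
class PrecisionParams:
    """Parameters of the localization-precision model.

    Defaults: σ = 140 nm PSF, 120 nm pixels, b² = 49 background photons,
    EMCCD excess noise on.
    """

    sigma_nm: float = 140.0
    pixel_nm: float = 120.0
    background_b2_photons: float = 49.0
    excess_noise: bool = True
    fwhm_factor: float = FWHM_FACTOR

    def __post_init__(self) -> None:
        if min(self.sigma_nm, self.pixel_nm, self.fwhm_factor) <= 0:
            raise ValueError("precision parameters must be positive")
        if self.background_b2_photons < 0:
            raise ValueError("b² must be >= 0")

    @property
    def sigma_a2_nm2(self) -> float:
        """Pixelation-corrected PSF variance σ² + a²/12 (nm²)."""
        return self.sigma_nm**2 + self.pixel_nm**2 / 12.0


@dataclass(frozen=True)
class DensityModel:
    """Label-density capacity model of the diffraction-limited region."""

    dlr_area_um2: float = 1.0
    spots_per_dlr: float = 1.0

    def __post_init__(self) -> None:
        if self.dlr_area_um2 <= 0 or self.spots_per_dlr <= 0:
            raise ValueError("density-model parameters must be positive")


def localization_resolution(N_photons, params: PrecisionParams = PrecisionParams()):
    """Photon-limited FWHM resolution (nm) for N detected photons.

    Strictly decreasing in N and increasing in b².  Accepts scalars or
    arrays.
    """
    N = np.asarray(N_photons, dtype=float)
    if np.any(N <= 0):
        raise ValueError("N_photons must be > 0")
    sa2 = params.sigma_a2_nm2
    var = (sa2 / N) * (
        16.0 / 9.0
        + 8.0 * math.pi * sa2 * params.background_b2_photons / (N * params.pixel_nm**2)
    )
    if params.excess_noise:
        var = 2.0 * var
    out = params.fwhm_factor * np.sqrt(var)
    return float(out) if np.isscalar(N_photons) else out


def nyquist_resolution(density_per_um2):
    """2D Nyquist-limited structural resolution (nm): R = 2/√n."""
    n = np.asarray(density_per_um2, dtype=float)
    if np.any(n <= 0):
        raise ValueError("density must be > 0")
    out = 2000.0 / np.sqrt(n)  # 2/√n in µm → nm
    return float(out) if np.isscalar(density_per_um2) else out


def density_capacity(ratio, model: DensityModel = DensityModel()):
    """Maximum tolerable label density (µm⁻²) for a τ_off/τ_on ratio."""
    r = np.asarray(ratio, dtype=float)
    if np.any(r < 0):
        raise ValueError("ratio must be >= 0")
    out = model.spots_per_dlr * r / model.dlr_area_um2
    return float(out) if np.isscalar(ratio) else out


def spots_per_fwhm_dlr(fwhm_nm: float) -> float:
    """Resolvable spot density (µm⁻²) when the DLR is a FWHM-sized disk."""
    if fwhm_nm <= 0:
        raise ValueError("fwhm must be > 0")
    r_um = fwhm_nm / 2.0 / 1000.0
    return 1.0 / (math.pi * r_um**2)


@dataclass
class ResolutionProfile:
    """Gain-vs-thiolate profile with fitted curves and bandpass edges."""

    thiolate_mM: np.ndarray
    photon_resolution_nm: np.ndarray
    nyquist_resolution_nm: np.ndarray
    gain_photon: np.ndarray              # point gains, normalized to [0, 1]
    gain_nyquist: np.ndarray
    photon_curve: Callable[[np.ndarray], np.ndarray]
    nyquist_curve: Callable[[np.ndarray], np.ndarray]
    grid_mM: np.ndarray
    gain_combined: np.ndarray            # normalized product on grid_mM
    bandpass: dict = field(default_factory=dict)
    n_scenario: str = "full_budget"

    def combined_at(self, c) -> np.ndarray:
        g = self.photon_curve(np.asarray(c, dtype=float)) * self.nyquist_curve(
            np.asarray(c, dtype=float)
        )
        return g / self._combined_max

    @property
    def _combined_max(self) -> float:
        raw = self.photon_curve(self.grid_mM) * self.nyquist_curve(self.grid_mM)
        return float(raw.max())


def _fit_single_exp(c: np.ndarray, g: np.ndarray) -> Callable:
    def f(x, y0, A, t):
        return y0 + A * np.exp(-x / t)

    # log-linear initial guess on the decaying part
    span = max(c.max() - c.min(), 1e-9)
    p0 = (g.min(), g[0] - g.min() if g[0] > g[-1] else g[-1] - g.min(), span / 3)
    popt, _ = curve_fit(f, c, g, p0=p0, maxfev=20000)
    return lambda x: f(np.asarray(x, dtype=float), *popt)


def _fit_double_exp(c: np.ndarray, g: np.ndarray) -> Callable:
    def f(x, y0, A1, t1, A2, t2):
        return y0 + A1 * np.exp(-x / t1) + A2 * np.exp(-x / t2)

    span = max(c.max() - c.min(), 1e-9)
    amp = g[-1] - g[0]
    p0 = (g.max(), -amp, span / 10, -amp / 2, span)
    popt, _ = curve_fit(f, c, g, p0=p0, maxfev=20000)
    return lambda x: f(np.asarray(x, dtype=float), *popt)


def _monotone_fallback(c: np.ndarray, g: np.ndarray, label: str) -> Callable:
    warnings.warn(f"{label} gain-curve fit failed; using monotone spline")
    interp = PchipInterpolator(c, g, extrapolate=True)
    return lambda x: np.asarray(interp(np.asarray(x, dtype=float)))


def gain_curves(
    thiolate_mM: Sequence[float],
    N_tau_on: Sequence[float],
    ratio: Sequence[float],
    params: PrecisionParams = PrecisionParams(),
    model: DensityModel = DensityModel(),
    n_scenario: str = "full_budget",
    budget_divisor: float = 2.0,
    levels: Sequence[float] = (0.707, 0.90),
    grid_points: int = 1024,
) -> ResolutionProfile:
    """Build the resolution-gain profile over a thiolate series.

    ``n_scenario`` selects the photon number entering the precision model:
    ``full_budget`` uses N = N_τon (the whole on-event budget in one
    localization); ``split_budget`` uses N = N_τon / budget_divisor
    (emission spread over frames uncorrelated with acquisition).

    The photon gain is fit with a single exponential, the Nyquist gain
    with a double exponential; the combined gain is the renormalised
    product of the two fitted curves.
    """
    c = np.asarray(thiolate_mM, dtype=float)
    order = np.argsort(c)
    c = c[order]
    if c.size < 4:
        raise ValueError("need >= 4 buffer points spanning a concentration range")
    if np.any(np.diff(c) <= 0):
        raise ValueError("duplicate thiolate concentrations")
    Nt = np.asarray(N_tau_on, dtype=float)[order]
    rt = np.asarray(ratio, dtype=float)[order]

    if n_scenario == "full_budget":
        N = Nt
    elif n_scenario == "split_budget":
        N = Nt / budget_divisor
    else:
        raise ValueError(f"unknown n_scenario {n_scenario!r}")

    res_photon = localization_resolution(N, params)
    res_nyq = nyquist_resolution(density_capacity(rt, model))
    gp = (1.0 / res_photon) / (1.0 / res_photon).max()
    gn = (1.0 / res_nyq) / (1.0 / res_nyq).max()

    try:
        curve_p = _fit_single_exp(c, gp)
    except (RuntimeError, TypeError):
        curve_p = _monotone_fallback(c, gp, "photon")
    try:
        # a double exponential needs at least 5 points
        curve_n = _fit_double_exp(c, gn)
    except (RuntimeError, TypeError):
        curve_n = _monotone_fallback(c, gn, "nyquist")

    grid = np.linspace(c.min(), c.max(), grid_points)
    raw = curve_p(grid) * curve_n(grid)
    profile = ResolutionProfile(
        thiolate_mM=c,
        photon_resolution_nm=res_photon,
        nyquist_resolution_nm=res_nyq,
        gain_photon=gp,
        gain_nyquist=gn,
        photon_curve=curve_p,
        nyquist_curve=curve_n,
        grid_mM=grid,
        gain_combined=raw / raw.max(),
        n_scenario=n_scenario,
    )
    for level in levels:
        profile.bandpass[level] = bandpass_edges(profile, level)
    return profile


def bandpass_edges(
    profile: ResolutionProfile, level: float
) -> tuple[float | None, float | None]:
    """Concentrations where the combined gain crosses ``level`` × max.

    Uses bisection on the fitted curves on each side of the peak.  A side
    on which the level is never attained yields ``None`` with a warning.
    """
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    grid = profile.grid_mM
    g = profile.combined_at(grid)
    i_peak = int(np.argmax(g))
    if level == 1.0:
        return (float(grid[i_peak]), float(grid[i_peak]))

    def f(x):
        return profile.combined_at(x) - level * g.max()

    low = high = None
    # left edge: last sign change below the peak
    below = np.nonzero(g[: i_peak + 1] < level * g.max())[0]
    if below.size:
        a = grid[below[-1]]
        b = grid[min(below[-1] + 1, i_peak)]
        low = float(brentq(f, a, b)) if f(a) * f(b) <= 0 else None
    else:
        warnings.warn("combined gain never falls below level on the low side")
    above_right = np.nonzero(g[i_peak:] < level * g.max())[0]
    if above_right.size:
        j = i_peak + above_right[0]
        high = float(brentq(f, grid[j - 1], grid[j])) if f(grid[j - 1]) * f(grid[j]) <= 0 else None
    else:
        warnings.warn("combined gain never falls below level on the high side")
    return (low, high)
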