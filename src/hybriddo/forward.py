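"""Closed-form photon-transport forward models for a semi-infinite medium.

Two solutions of the diffusion approximation with an extrapolated boundary
are provided, both standard for single-distance reflectance probes:

* time-domain diffuse reflectance ``td_reflectance`` — the shape of the
  photon distribution of time-of-flight (DTOF) recorded by time-resolved
  spectroscopy (TRS);
* the normalized field autocorrelation ``dcs_g1`` of the correlation
  diffusion equation with Brownian scatterer dynamics — the decay measured
  by diffuse correlation spectroscopy (DCS), mapped to the measured
  intensity autocorrelation via the Siegert relation ``siegert_g2``.

Curves are reported up to an arbitrary amplitude: downstream fits treat the
scale as a nuisance parameter, so only the shape carries information.
Units: lengths in mm, DTOF time grids in ps, correlation lags in s, the
blood-flow index (BFI) in cm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPEED_OF_LIGHT_MM_PER_PS",
    "OpticalProperties",
    "MediumGeometry",
    "DCSConfig",
    "effective_reflection_coefficient",
    "td_reflectance",
    "dcs_g1",
    "siegert_g2",
    "convolve_with_irf",
]

#: vacuum speed of light in mm/ps
SPEED_OF_LIGHT_MM_PER_PS = 0.299792458


class ValidationError(ValueError):
    """Raised when a physically meaningless parameter is supplied."""


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering of a homogeneous tissue volume.

    Parameters
    ----------
    wavelength : float
        Wavelength in nm (identifies the laser line; not used in the math).
    mua : float
        Absorption coefficient, 1/mm.
    musp : float
        Reduced scattering coefficient, 1/mm.
    """

    wavelength: float
    mua: float
    musp: float

    def __post_init__(self) -> None:
        if not (self.mua > 0.0):
            raise ValidationError(f"mua must be > 0, got {self.mua}")
        if not (self.musp > 0.0):
            raise ValidationError(f"musp must be > 0, got {self.musp}")

    @property
    def diffusion_regime(self) -> bool:
        """True when musp > mua, the validity condition of diffusion theory."""
        return self.musp > self.mua


@dataclass(frozen=True)
class MediumGeometry:
    """Source-detector separation and refractive indices of the half-space."""

    rho: float  # source-detector separation, mm
    n_tissue: float = 1.4
    n_outside: float = 1.0

    def __post_init__(self) -> None:
        if not (self.rho > 0.0):
            raise ValidationError(f"rho must be > 0, got {self.rho}")
        if self.n_tissue < 1.0 or self.n_outside < 1.0:
            raise ValidationError("refractive indices must be >= 1")

    @property
    def v(self) -> float:
        """Speed of light in the tissue, mm/ps."""
        return SPEED_OF_LIGHT_MM_PER_PS / self.n_tissue


@dataclass(frozen=True)
class DCSConfig:
    """DCS model configuration: laser line, Brownian flow index, coherence."""

    wavelength: float = 785.0  # nm
    bfi: float = 1e-8  # cm^2/s
    beta: float = 0.5

    def __post_init__(self) -> None:
        if self.bfi < 0.0:
            raise ValidationError(f"bfi must be >= 0, got {self.bfi}")
        if not (0.0 < self.beta <= 1.0):
            raise ValidationError(f"beta must be in (0, 1], got {self.beta}")


def effective_reflection_coefficient(n_tissue: float, n_outside: float = 1.0) -> float:
    """Effective Fresnel reflection coefficient of the tissue boundary.

    Polynomial approximation in the relative index n = n_tissue/n_outside,
    used to place the extrapolated zero-fluence boundary.
    """
    n = n_tissue / n_outside
    return -1.440 * n**-2 + 0.710 * n**-1 + 0.668 + 0.0636 * n


def _boundary_depths(props: OpticalProperties, geom: MediumGeometry):
    """Isotropic-source depth z0, extrapolation length zb and diffusion D."""
    D = 1.0 / (3.0 * props.musp)  # mm
    z0 = 1.0 / props.musp
    reff = effective_reflection_coefficient(geom.n_tissue, geom.n_outside)
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
    return D, z0, zb


def td_reflectance(
    props: OpticalProperties, geom: MediumGeometry, time_grid: np.ndarray
) -> np.ndarray:
    """Time-domain diffuse reflectance of a semi-infinite medium.

    Extrapolated-boundary solution with an isotropic source at depth
    z0 = 1/musp and its negative image across the extrapolated boundary.
    The returned amplitude is arbitrary (shape only).

    Parameters
    ----------
    time_grid : array
        Strictly increasing photon arrival times, ps, all > 0.

    Returns
    -------
    array
        Nonnegative photon-arrival density on ``time_grid``. For large t the
        log-slope tends to -mua*v with v = c/n_tissue (physics self-test).
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("time_grid must be a nonempty 1-D array")
    if np.any(t <= 0.0) or np.any(np.diff(t) <= 0.0):
        raise ValidationError("time_grid must be strictly increasing and > 0")

    D, z0, zb = _boundary_depths(props, geom)
    v = geom.v
    four_Dvt = 4.0 * D * v * t
    # work in log space to keep very late times finite
    log_common = (
        -props.mua * v * t - geom.rho**2 / four_Dvt - 2.5 * np.log(t)
    )
    pos = z0 * np.exp(-(z0**2) / four_Dvt)
    neg = (z0 + 2.0 * zb) * np.exp(-((z0 + 2.0 * zb) ** 2) / four_Dvt)
    out = np.exp(log_common) * (pos + neg)
    return np.where(np.isfinite(out), out, 0.0)


def dcs_g1(
    props_785: OpticalProperties,
    geom: MediumGeometry,
    cfg: DCSConfig,
    tau_grid: np.ndarray,
) -> np.ndarray:
    """Normalized field autocorrelation g1(tau) for Brownian dynamics.

    Solution of the correlation diffusion equation for the semi-infinite
    extrapolated-boundary geometry, with mean-square displacement
    ``6*BFI*tau`` and optical wavenumber ``k0 = 2*pi*n_tissue/lambda``.
    """
    tau = np.asarray(tau_grid, dtype=float)
    if np.any(tau < 0.0) or np.any(np.diff(tau) <= 0.0):
        raise ValidationError("tau_grid must be nonnegative and increasing")
    if cfg.bfi < 0.0:
        raise ValidationError("bfi must be >= 0")

    D, z0, zb = _boundary_depths(props_785, geom)
    r1 = np.hypot(geom.rho, z0)
    rb = np.hypot(geom.rho, z0 + 2.0 * zb)

    lam_mm = cfg.wavelength * 1e-6
    k0 = 2.0 * np.pi * geom.n_tissue / lam_mm  # 1/mm
    bfi_mm = cfg.bfi * 100.0  # cm^2/s -> mm^2/s

    # K^2(tau) = 3 mua musp + musp^2 k0^2 <dr^2(tau)>, <dr^2> = 6 BFI tau
    k_sq = 3.0 * props_785.mua * props_785.musp + 6.0 * (
        props_785.musp**2
    ) * (k0**2) * bfi_mm * tau
    k_tau = np.sqrt(k_sq)

    def green(k):
        return np.exp(-k * r1) / r1 - np.exp(-k * rb) / rb

    g0 = green(np.sqrt(3.0 * props_785.mua * props_785.musp))
    return green(k_tau) / g0


def siegert_g2(g1: np.ndarray, beta: float) -> np.ndarray:
    """Intensity autocorrelation from the field autocorrelation.

    g2 = 1 + beta * g1**2, with beta the coherence factor in (0, 1].
    """
    if not (0.0 < beta <= 1.0):
        raise ValidationError(f"beta must be in (0, 1], got {beta}")
    g1 = np.asarray(g1, dtype=float)
    return 1.0 + beta * g1**2


def convolve_with_irf(
    model_curve: np.ndarray,
    irf: np.ndarray,
    bin_width: float,
    irf_bin_width: float | None = None,
) -> np.ndarray:
    """Causal discrete convolution of a model DTOF with the instrument IRF.

    Both curves must share the bin width. The output is truncated to the
    model length (the measured acquisition window); a unit-impulse IRF at
    bin 0 returns the input unchanged.
    """
    if irf_bin_width is not None and not np.isclose(irf_bin_width, bin_width):
        raise ValidationError(
            f"bin widths differ: model {bin_width} ps vs irf {irf_bin_width} ps"
        )
    model = np.asarray(model_curve, dtype=float)
    kernel = np.asarray(irf, dtype=float)
    return np.convolve(model, kernel)[: model.size]
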