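"""Projection-imaging geometry: distances, blurs and Fresnel numbers.

A point-projection (cone-beam) in-line imaging setup is described by the
total source-to-detector distance ``R = R1 + R2``, the geometric
magnification ``M = (R1 + R2)/R1``, and Gaussian blur widths: the source
intensity distribution (sigma_src), the detector line-spread function
(sigma_det) and an optional intrinsic unsharpness of the imaged edge
(sigma_obj).  All object-side quantities are expressed in the object
plane; the system LSF standard deviation referred to that plane is

    sigma_sys(M) = sqrt[(M-1)^2 sigma_src^2 + sigma_det^2] / M

which interpolates between the detector blur at contact (M = 1) and the
source blur at M -> infinity, with a unique minimum at
M_res = 1 + (sigma_det/sigma_src)^2.

Free-space propagation strength is measured by the minimal Fresnel
number N_F = 4 pi sigma_M^2 / (lambda R') with effective defocus
distance R' = R2/M; the phase-fringe gain of a monomorphous feature is
gamma/N_F.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from .materials import energy_to_wavelength

__all__ = [
    "Geometry",
    "m_res",
    "sigma_sys",
    "sigma_M",
    "effective_distance",
    "fresnel_number",
    "width",
]

#: Å per µm (wavelengths are quoted in Å, lengths handled in µm).
UM_PER_ANGSTROM = 1.0e-4
UM_PER_M = 1.0e6


@dataclass(frozen=True)
class Geometry:
    """Cone-beam imaging geometry.

    Parameters
    ----------
    R : float
        Total source-to-detector distance R1 + R2, in metres.
    M : float
        Geometric magnification (R1 + R2)/R1, >= 1.
    sigma_src : float
        Source-blur standard deviation, µm.
    sigma_det : float
        Detector LSF standard deviation, µm.
    sigma_obj : float, optional
        Intrinsic unsharpness of the imaged edge, µm (default 0:
        a sharp edge).
    """

    R: float
    M: float
    sigma_src: float
    sigma_det: float
    sigma_obj: float = 0.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.M < 1:
            raise ValueError("magnification must be >= 1")
        if self.sigma_src <= 0 or self.sigma_det <= 0:
            raise ValueError("sigma_src and sigma_det must be positive")
        if self.sigma_obj < 0:
            raise ValueError("sigma_obj must be non-negative")

    @property
    def R1(self) -> float:
        """Source-to-sample distance, m."""
        return self.R / self.M

    @property
    def R2(self) -> float:
        """Sample-to-detector distance, m."""
        return self.R * (self.M - 1.0) / self.M

    def with_magnification(self, M: float) -> "Geometry":
        return replace(self, M=M)

    def sigma_sys(self) -> float:
        return sigma_sys(self)

    def sigma_M(self) -> float:
        return sigma_M(self)

    def effective_distance(self) -> float:
        return effective_distance(self)

    def fresnel_number(self, energy_keV: float) -> float:
        return fresnel_number(self, energy_keV)


def sigma_sys(g: Geometry) -> float:
    """System LSF standard deviation in the object plane, µm."""
    return math.hypot((g.M - 1.0) * g.sigma_src, g.sigma_det) / g.M


def m_res(sigma_src: float, sigma_det: float) -> float:
    """Magnification minimizing sigma_sys: M_res = 1 + (sigma_det/sigma_src)^2."""
    if sigma_src <= 0 or sigma_det <= 0:
        raise ValueError("blur widths must be positive")
    return 1.0 + (sigma_det / sigma_src) ** 2


def sigma_M(g: Geometry) -> float:
    """Total edge blur sqrt(sigma_obj^2 + sigma_sys^2), µm.

    Gaussian blurs convolve by adding variances, so the intrinsic edge
    unsharpness and the system LSF combine in quadrature.
    """
    return math.hypot(g.sigma_obj, sigma_sys(g))


def effective_distance(g: Geometry) -> float:
    """Effective propagation ("defocus") distance R' = R2/M = R(M-1)/M^2, m."""
    return g.R * (g.M - 1.0) / g.M**2


def fresnel_number(g: Geometry, energy_keV: float) -> float:
    """Minimal Fresnel number N_F = 4 pi sigma_M^2 / (lambda R').

    Dimensionless; the phase-fringe gain is gamma/N_F.  At contact
    (M = 1) there is no propagation and N_F is reported as +inf with a
    warning.
    """
    if energy_keV <= 0:
        raise ValueError("photon energy must be positive")
    if g.M == 1.0:
        warnings.warn(
            "contact geometry (M = 1): no propagation, Fresnel number is infinite",
            stacklevel=2,
        )
        return math.inf
    lam_um = energy_to_wavelength(energy_keV) * UM_PER_ANGSTROM
    rprime_um = effective_distance(g) * UM_PER_M
    return 4.0 * math.pi * sigma_M(g) ** 2 / (lam_um * rprime_um)


def width(sigma: float) -> float:
    """Equivalent width Delta = sqrt(2 pi) sigma of a unit-area Gaussian, µm."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return math.sqrt(2.0 * math.pi) * sigma
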