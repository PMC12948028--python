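"""Image-quality metrics: propagation contrast, SNR, CNR and the
dose-normalized 2D/3D imaging-quality characteristics.

The propagation contrast of a sharp monomorphous edge is the relative
fluence difference between the first-fringe extrema at x = -+ sigma_M:

    C = (1 - q)/(1 + q) + (2 pi e)^(-1/2) * q * (gamma/N_F) * (µT)_max

with q = exp[-(µT)_max]; the first addend is absorption contrast, the
second phase contrast.  CNR multiplies the contrast by the
per-resolution-element Poisson SNR.  The 2D/3D quality characteristics
additionally normalize by spatial resolution and absorbed dose; their
absolute scale is an internal convention (only argmax locations, ratios
and scaling laws are physically meaningful here), and both factorize
into a geometry term (function of M alone) times an energy term, so the
M-optimum is energy-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import geometry as geo
from .forward_model import EdgeProfile, Sample, XG_MAX, VALIDITY_THRESHOLD, validity_ratio
from .materials import Material, UM_PER_CM, energy_to_wavelength

__all__ = [
    "MetricResult",
    "contrast",
    "contrast_from_profile",
    "snr",
    "cnr",
    "q2d",
    "q3d",
    "constants",
]


@dataclass(frozen=True)
class MetricResult:
    """A metric value with its additive components and input echo."""

    value: float
    components: dict[str, float] = field(default_factory=dict)
    inputs_echo: dict[str, Any] = field(default_factory=dict)

    def __float__(self) -> float:
        return self.value


def _mu_t_max(material: Material, energy_keV: float, T_cm: float) -> float:
    return material.at(energy_keV).mu * T_cm * UM_PER_CM


def _echo(g: geo.Geometry, material: Material, energy_keV: float, **extra) -> dict:
    echo = {
        "M": g.M,
        "energy_keV": energy_keV,
        "R_m": g.R,
        "sigma_src_um": g.sigma_src,
        "sigma_det_um": g.sigma_det,
        "material": type(material).__name__,
    }
    echo.update(extra)
    return echo


def contrast(
    g: geo.Geometry, material: Material, energy_keV: float, sample: Sample
) -> MetricResult:
    """Propagation contrast of the edge: absorption + phase addends.

    For M = 1 (contact) the phase addend vanishes.  Values are reported
    raw even when the near-Fresnel validity condition is violated; the
    validity flag travels in ``inputs_echo``.
    """
    mu_t = _mu_t_max(material, energy_keV, sample.T)
    q = math.exp(-mu_t)
    absorption = (1.0 - q) / (1.0 + q)
    if g.M == 1.0:
        gain = 0.0
        vratio = math.inf
    else:
        gain = material.at(energy_keV).gamma / geo.fresnel_number(g, energy_keV)
        vratio = validity_ratio(g, material, energy_keV, sample.T)
    phase = XG_MAX * q * gain * mu_t
    return MetricResult(
        value=absorption + phase,
        components={"absorption": absorption, "phase": phase},
        inputs_echo=_echo(
            g, material, energy_keV,
            validity_ratio=vratio, validity_ok=vratio > VALIDITY_THRESHOLD,
        ),
    )


def contrast_from_profile(profile: EdgeProfile) -> float:
    """Fringe-sampled contrast [I(-s) - I(+s)] / [I(-s) + I(+s)], s = sigma_M.

    Serves as the sampled-profile oracle for :func:`contrast`; linear
    interpolation is used when ±sigma_M fall between grid points.
    """
    if not np.any(profile.fluence != 0):
        raise ValueError("degenerate all-zero profile")
    s = profile.sigma_M
    i_minus = float(np.interp(-s, profile.x, profile.fluence))
    i_plus = float(np.interp(s, profile.x, profile.fluence))
    denom = i_minus + i_plus
    if denom == 0:
        raise ValueError("degenerate profile: zero fluence at the fringe points")
    return (i_minus - i_plus) / denom


def snr(
    g: geo.Geometry,
    material: Material,
    energy_keV: float,
    sample: Sample,
    I_in: float = 1.0,
    eta: float = 1.0,
) -> float:
    """Per-resolution-element SNR under Poisson counting statistics.

    SNR = sqrt(eta * I_in * A_n * exp[-mu0*T0 - (µT)_max]) / M with
    noise-collection area A_n = 2 pi sigma_det^2 (the detector PSF
    equivalent area); the 1/M factor is the fluence dilution of the
    magnified image.
    """
    if I_in < 0:
        raise ValueError("I_in must be non-negative")
    props = material.at(energy_keV)
    attenuation = props.mu0 * sample.T0 * UM_PER_CM + props.mu * sample.T * UM_PER_CM
    area = 2.0 * math.pi * g.sigma_det**2
    return math.sqrt(eta * I_in * area * math.exp(-attenuation)) / g.M


def cnr(
    g: geo.Geometry,
    material: Material,
    energy_keV: float,
    sample: Sample,
    I_in: float = 1.0,
    eta: float = 1.0,
) -> MetricResult:
    """Contrast-to-noise ratio: contrast times the Poisson SNR.

    ``components`` carries the absorption and phase contrast addends
    each multiplied by the SNR; the phase component is the quantity
    whose M-argmax obeys the (M-1)^2 (2M-1) = (sigma_det/sigma_src)^2
    relation.
    """
    c = contrast(g, material, energy_keV, sample)
    s = snr(g, material, energy_keV, sample, I_in, eta)
    return MetricResult(
        value=c.value * s,
        components={
            "absorption": c.components["absorption"] * s,
            "phase": c.components["phase"] * s,
        },
        inputs_echo=c.inputs_echo,
    )


def _s_det_plane(g: geo.Geometry, M: float | None = None) -> float:
    """Detector-plane blur s(M) = sqrt[(M-1)^2 sigma_src^2 + sigma_det^2], µm."""
    m = g.M if M is None else M
    return math.hypot((m - 1.0) * g.sigma_src, g.sigma_det)


def q2d(
    g: geo.Geometry,
    material: Material,
    energy_keV: float,
    sample: Sample,
    eta: float = 1.0,
) -> MetricResult:
    """Dose-normalized 2D imaging-quality characteristic.

    value = eta^(1/2) (2 pi e)^(-1/2) * W2(E) * G2(M) with the
    energy factor
    W2 = gamma*lambda*(µT)_max * exp[-(µT)_max - mu0*T0/2] * K^(-1/2)
    and geometry factor G2 = R (M-1) / s(M)^3,
    s(M) = sqrt[(M-1)^2 sigma_src^2 + sigma_det^2].  Only the phase
    (fringe) contrast enters, as appropriate for a weakly absorbing
    edge.  Internal units: lambda in Å, R in m, s in µm; the absolute
    scale is a fixed convention.
    """
    props = material.at(energy_keV)
    lam = energy_to_wavelength(energy_keV)
    mu_t = props.mu * sample.T * UM_PER_CM
    w2 = (
        props.gamma
        * lam
        * mu_t
        * math.exp(-mu_t - props.mu0 * sample.T0 * UM_PER_CM / 2.0)
        / math.sqrt(props.k)
    )
    g2 = g.R * (g.M - 1.0) / _s_det_plane(g) ** 3
    value = math.sqrt(eta) * XG_MAX * w2 * g2
    return MetricResult(
        value=value,
        components={"energy_factor": w2, "geometry_factor": g2},
        inputs_echo=_echo(g, material, energy_keV),
    )


def q3d(
    g: geo.Geometry,
    material: Material,
    energy_keV: float,
    sample: Sample,
    R_CT_cm: float,
    eta: float = 1.0,
    f_corr=None,
) -> MetricResult:
    """Dose-normalized 3D (CT) imaging-quality characteristic.

    value = kappa3 * F(M) * W3(E) * f_corr with the geometry factor
    F(M) = R M^(1/2) (M-1) / s(M)^(7/2) and energy factor
    W3 = gamma*lambda * K^(-1/2) * µ(λ)L * exp[-mu0*T0/2],
    where L = pi R_CT / 2 is the mean CT chord length of the
    reconstructed cylinder of radius R_CT.  The slowly varying
    correction f(M, λ) is neglected analytically (f_corr = 1) by
    default; a callable ``f_corr(M, energy_keV) -> float`` may be
    supplied to include one.  kappa3 = 1 internal convention.
    """
    if R_CT_cm <= 0:
        raise ValueError("R_CT must be positive")
    props = material.at(energy_keV)
    lam = energy_to_wavelength(energy_keV)
    L_um = math.pi * R_CT_cm * UM_PER_CM / 2.0
    w3 = (
        props.gamma
        * lam
        / math.sqrt(props.k)
        * props.mu
        * L_um
        * math.exp(-props.mu0 * sample.T0 * UM_PER_CM / 2.0)
    )
    f_geom = g.R * math.sqrt(g.M) * (g.M - 1.0) / _s_det_plane(g) ** 3.5
    corr = 1.0 if f_corr is None else float(f_corr(g.M, energy_keV))
    value = math.sqrt(eta) * f_geom * w3 * corr
    return MetricResult(
        value=value,
        components={"energy_factor": w3, "geometry_factor": f_geom, "f_corr": corr},
        inputs_echo=_echo(g, material, energy_keV, R_CT_cm=R_CT_cm),
    )


def constants() -> tuple[float, float]:
    """The two closed-form constants of the fully optimized contrast.

    a0 = (1 - e^(-2/3)) / (1 + e^(-2/3)) ~= 0.322 is the absorption
    contrast at the optimal edge transmission e^(-2/3); c0 =
    (2/3) e^(-2/3) (2 pi e)^(-1/2) ~= 0.083 multiplies the phase term.
    """
    e23 = math.exp(-2.0 / 3.0)
    a0 = (1.0 - e23) / (1.0 + e23)
    c0 = (2.0 / 3.0) * e23 * XG_MAX
    return a0, c0
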