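"""Optimal magnification and X-ray energy under each image-quality metric.

For a fixed total source-to-detector distance the geometry factor of
every metric depends on the magnification M only through the ratio
r = sigma_det/sigma_src, giving closed forms or monotone one-dimensional
root equations:

================  =============================================
resolution        M_res = 1 + r^2
contrast          M_C   = 1 + r
CNR               r = (M - 1)(2M - 1)^(1/2)
Q_2D              M_Q2  = 1 + r/sqrt(2)
Q_3D (CT)         r = (M - 1)[(4M + 1)/(3M - 1)]^(1/2)
================  =============================================

The cubic equations behind the CNR and Q_3D rows are solved by
bracketed root-finding on their monotone inverse forms rather than by
Cardano's formula.  Energy optima follow from transmission conditions:
edge transmission e^(-2/3) for contrast, bulk transmission e^(-4) for
CNR and e^(-2) for the dose-normalized quality factors (under the
lambda-linear bulk attenuation law).  A grid + golden-section numeric
optimizer cross-checks any metric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import optimize as sopt

from .forward_model import Sample
from .geometry import m_res
from .materials import Material, UM_PER_CM

__all__ = [
    "Optimum",
    "opt_m_resolution",
    "opt_m_contrast",
    "opt_m_cnr",
    "opt_m_q2d",
    "opt_m_q3d",
    "r2_at",
    "opt_e_transmission",
    "opt_numeric",
]

Criterion = Literal["resolution", "contrast", "cnr", "q2d", "q3d"]


@dataclass(frozen=True)
class Optimum:
    """An optimizer result: where the optimum is and how it was found."""

    criterion: str
    axis: Literal["magnification", "energy"]
    value: float
    achieved: float | None = None
    method: str = "closed_form"


def _check_sigmas(sigma_src: float, sigma_det: float) -> float:
    if sigma_src <= 0 or sigma_det <= 0:
        raise ValueError("blur widths must be positive")
    return sigma_det / sigma_src


def opt_m_resolution(sigma_src: float, sigma_det: float) -> Optimum:
    """Magnification minimizing the system blur: M_res = 1 + r^2."""
    _check_sigmas(sigma_src, sigma_det)
    return Optimum("resolution", "magnification", m_res(sigma_src, sigma_det))


def opt_m_contrast(sigma_src: float, sigma_det: float) -> Optimum:
    """Contrast-optimal magnification M_C = 1 + sigma_det/sigma_src.

    At M_C the source and detector blurs contribute equally:
    sigma_src (M_C - 1) = sigma_det.
    """
    r = _check_sigmas(sigma_src, sigma_det)
    return Optimum("contrast", "magnification", 1.0 + r)


def _bracketed_root(gfun: Callable[[float], float], target: float, hi: float) -> float:
    """Root of gfun(M) = target on (1, hi]; gfun monotone increasing, gfun(1)=0."""
    if target == 0.0:
        return 1.0
    sol = sopt.brentq(lambda m: gfun(m) - target, 1.0, hi, xtol=1e-14, rtol=1e-15)
    return float(sol)


def opt_m_cnr(sigma_src: float, sigma_det: float) -> Optimum:
    """CNR-optimal magnification: root of (M-1)^2 (2M-1) = r^2, M > 1.

    Equivalently r = (M-1)(2M-1)^(1/2), the monotone look-up form.
    Always below M_C = 1 + r since photon noise penalizes source blur
    more than detector blur.
    """
    r = _check_sigmas(sigma_src, sigma_det)
    root = _bracketed_root(lambda m: (m - 1.0) * math.sqrt(2.0 * m - 1.0), r, 1.0 + r)
    return Optimum("cnr", "magnification", root, method="cubic_root")


def opt_m_q2d(sigma_src: float, sigma_det: float) -> Optimum:
    """2D-quality-optimal magnification M_Q2 = 1 + r/sqrt(2)."""
    r = _check_sigmas(sigma_src, sigma_det)
    return Optimum("q2d", "magnification", 1.0 + r / math.sqrt(2.0))


def opt_m_q3d(sigma_src: float, sigma_det: float) -> Optimum:
    """3D-quality-optimal magnification: root of
    (M-1)^2 (4M+1)/(3M-1) = r^2, M > 1 (analytic mode, the slowly
    varying correction f(M, λ) neglected)."""
    r = _check_sigmas(sigma_src, sigma_det)
    root = _bracketed_root(
        lambda m: (m - 1.0) * math.sqrt((4.0 * m + 1.0) / (3.0 * m - 1.0)),
        r,
        1.0 + r,
    )
    return Optimum("q3d", "magnification", root, method="cubic_root")


def r2_at(M: float, R: float) -> float:
    """Sample-to-detector distance R2 = R (M-1)/M at magnification M, m."""
    if M < 1 or R <= 0:
        raise ValueError("need M >= 1 and R > 0")
    return R * (M - 1.0) / M


#: exponent targets of the transmission conditions, per criterion
_TRANSMISSION_TARGETS = {
    "contrast": ("edge", 2.0 / 3.0),  # exp[-(µT)_max] = e^(-2/3)
    "cnr": ("bulk", 4.0),  #             exp[-mu0 T0]  = e^(-4)
    "q2d": ("bulk", 2.0),  #             exp[-mu0 T0]  = e^(-2)
    "q3d": ("bulk", 2.0),
}


def opt_e_transmission(
    material: Material,
    sample: Sample,
    criterion: Criterion,
    bracket: tuple[float, float] = (5.0, 150.0),
) -> Optimum:
    """Optimal X-ray energy from the criterion's transmission condition.

    Solves exp[-(µT)_max(E)] = e^(-2/3) (contrast), exp[-mu0(E) T0] =
    e^(-4) (CNR) or e^(-2) (q2d/q3d) for E in keV by bracketed
    root-finding; the constants are kept exact, not their rounded
    0.51/0.02/0.135 forms.  Independent of geometry.
    """
    if criterion not in _TRANSMISSION_TARGETS:
        raise ValueError(
            f"criterion {criterion!r} has no transmission condition "
            f"(choose from {sorted(_TRANSMISSION_TARGETS)})"
        )
    which, target = _TRANSMISSION_TARGETS[criterion]

    def exponent(E: float) -> float:
        props = material.at(E)
        if which == "edge":
            return props.mu * sample.T * UM_PER_CM
        return props.mu0 * sample.T0 * UM_PER_CM

    lo, hi = bracket
    f_lo, f_hi = exponent(lo) - target, exponent(hi) - target
    if f_lo * f_hi > 0:
        raise ValueError(
            f"transmission condition for {criterion!r} "
            f"(target exponent {target:.6g} on the {which} attenuation) has no "
            f"root in [{lo}, {hi}] keV"
        )
    root = sopt.brentq(lambda E: exponent(E) - target, lo, hi, xtol=1e-12, rtol=1e-14)
    return Optimum(criterion, "energy", float(root), method="transmission_condition")


def opt_numeric(
    metric_fn: Callable[[float], float],
    axis: Literal["magnification", "energy"],
    bracket: tuple[float, float],
    tol: float | None = None,
    n_coarse: int = 512,
    criterion: str = "numeric",
) -> Optimum:
    """Numeric argmax of a scalar metric over a bracket.

    A 512-point coarse grid locates the maximum, then golden-section
    refinement narrows it to ``tol`` (default 1e-4 in M, 0.05 keV in E).
    If the coarse scan reveals multiple interior maxima the global grid
    maximum is returned with a multimodality warning.
    """
    lo, hi = bracket
    if not (np.isfinite(lo) and np.isfinite(hi)) or hi <= lo:
        raise ValueError(f"invalid bracket {bracket}")
    if tol is None:
        tol = 1e-4 if axis == "magnification" else 0.05

    grid = np.linspace(lo, hi, n_coarse)
    vals = np.array([metric_fn(v) for v in grid])
    i = int(np.argmax(vals))

    interior = (vals[1:-1] > vals[:-2]) & (vals[1:-1] >= vals[2:])
    if interior.sum() > 1:
        warnings.warn(
            "metric appears multimodal on the coarse grid; returning the "
            "global grid maximum",
            stacklevel=2,
        )
        return Optimum(criterion, axis, float(grid[i]), float(vals[i]), "grid")

    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_coarse - 1)]
    res = sopt.minimize_scalar(
        lambda v: -metric_fn(v), bounds=(a, b), method="bounded",
        options={"xatol": tol / 4.0},
    )
    return Optimum(
        criterion, axis, float(res.x), float(-res.fun), "golden_section"
    )
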