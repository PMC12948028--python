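"""Optical and dosimetric properties of the bulk/feature material pair.

A propagation-based imaging (PBI) sample is modelled as a uniform "bulk"
slab of thickness ``T0`` containing a thin "edge" feature of thickness
``T`` whose refractive-index difference with the bulk is monomorphous:
``delta = gamma * beta`` with a single ratio ``gamma`` throughout the
feature.  All image-quality metrics then depend on the material only
through three optical constants and one dosimetric one:

``mu0``
    linear attenuation coefficient of the bulk (1/µm),
``mu``
    feature-minus-bulk attenuation contrast ``mu1 - mu0`` (1/µm),
``gamma``
    ratio ``delta/beta`` of the refractive-index decrement to the
    absorption index (the phase-contrast lever arm, dimensionless),
``K``
    dose-conversion coefficient: mean absorbed dose in the material
    relative to the entrance air kerma at a fixed reference energy.

Away from absorption edges these follow simple wavelength power laws for
soft tissue at hard X-ray energies: ``mu ∝ λ³``, ``mu0 ∝ λ`` (empirically
almost linear for adipose tissue in the 20-40 keV band), ``γλ ∝ λ⁻¹``
(so ``γ ∝ λ⁻²``) and ``K ∝ λ²``.  :class:`MaterialModel` encodes those
laws around an anchor energy; :class:`MaterialTable` interpolates a
measured/tabulated set of values log-log instead.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Union

import numpy as np

__all__ = [
    "HC_KEV_ANGSTROM",
    "CM_PER_UM",
    "energy_to_wavelength",
    "OpticalProperties",
    "MaterialModel",
    "MaterialTable",
    "Material",
    "evaluate",
    "edge_transmission_min",
    "bulk_transmission",
    "cm_contrast",
]

#: hc in keV·Å, fixing the photon energy <-> wavelength conversion.
HC_KEV_ANGSTROM = 12.3984198

#: µm per cm; thicknesses are accepted in cm and converted on entry.
UM_PER_CM = 1.0e4
CM_PER_UM = 1.0 / UM_PER_CM


def energy_to_wavelength(energy_keV: float) -> float:
    """Convert photon energy (keV) to wavelength (Å), λ = hc/E.

    >>> round(energy_to_wavelength(32.0), 5)
    0.38745
    """
    energy_keV = float(energy_keV)
    if energy_keV <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_keV}")
    return HC_KEV_ANGSTROM / energy_keV


class OpticalProperties(NamedTuple):
    """Optical constants of the material pair at one photon energy."""

    mu0: float  #: bulk linear attenuation coefficient (1/µm)
    mu: float  #: feature-minus-bulk attenuation contrast (1/µm)
    gamma: float  #: delta/beta ratio of the feature (dimensionless)
    k: float  #: dose-conversion coefficient K(λ, λ0) (dimensionless)


@dataclass(frozen=True)
class MaterialModel:
    """Power-law material model anchored at a reference energy.

    Each property equals its anchor value times ``(λ/λ0)**p`` with the
    exponent listed below.  ``p_gamma_lambda`` is the exponent of the
    *product* ``γ(λ)λ``, so ``γ`` itself scales as ``λ**(p_gamma_lambda-1)``
    (default ``λ⁻²``).

    Parameters
    ----------
    ref_energy : float
        Anchor photon energy λ0 is derived from, in keV.
    mu0_ref, mu_ref : float
        Bulk attenuation and feature attenuation contrast at the anchor,
        in 1/µm.
    gamma_ref : float
        delta/beta ratio at the anchor.
    k_ref : float
        K(λ0, λ0); defaults to 1 since only the λ-dependence of K enters
        any optimum.
    p_mu0, p_mu, p_gamma_lambda, p_k : float
        Wavelength power-law exponents (defaults 1, 3, -1, 2).  A
        quadratic bulk law can be selected with ``p_mu0=2``.
    """

    ref_energy: float
    mu0_ref: float
    mu_ref: float
    gamma_ref: float
    k_ref: float = 1.0
    p_mu0: float = 1.0
    p_mu: float = 3.0
    p_gamma_lambda: float = -1.0
    p_k: float = 2.0

    def __post_init__(self) -> None:
        if self.ref_energy <= 0:
            raise ValueError("ref_energy must be positive")
        for name in ("mu0_ref", "mu_ref", "gamma_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def k_ref_energy(self) -> float:
        return self.ref_energy

    def at(self, energy_keV: float) -> OpticalProperties:
        """Optical properties at ``energy_keV`` from the power laws."""
        energy_keV = float(energy_keV)
        if energy_keV <= 0:
            raise ValueError("photon energy must be positive")
        # λ/λ0 = E0/E
        ratio = self.ref_energy / energy_keV
        gamma_lambda = (
            self.gamma_ref
            * energy_to_wavelength(self.ref_energy)
            * ratio**self.p_gamma_lambda
        )
        return OpticalProperties(
            mu0=self.mu0_ref * ratio**self.p_mu0,
            mu=self.mu_ref * ratio**self.p_mu,
            gamma=gamma_lambda / energy_to_wavelength(energy_keV),
            k=self.k_ref * ratio**self.p_k,
        )


@dataclass(frozen=True)
class MaterialTable:
    """Tabulated material properties with log-log interpolation.

    Rows are (energy keV, mu0 1/µm, mu 1/µm, gamma) with strictly
    increasing energy.  Between rows each column is interpolated linearly
    in log-log space (a local power law); outside the tabulated span the
    nearest segment's slope extrapolates, with a warning beyond
    [Emin/2, 2·Emax].  The dose-conversion coefficient has no tabulated
    column and follows the λ² power law anchored at ``k_ref_energy``.
    """

    energies: np.ndarray
    mu0: np.ndarray
    mu: np.ndarray
    gamma: np.ndarray
    k_ref: float = 1.0
    k_ref_energy: float | None = None
    p_k: float = 2.0

    def __post_init__(self) -> None:
        for name in ("energies", "mu0", "mu", "gamma"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        e = self.energies
        if e.size < 2:
            raise ValueError("MaterialTable needs at least 2 rows")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energies must be strictly increasing")
        for name in ("energies", "mu0", "mu", "gamma"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"all {name} entries must be positive")
        if self.k_ref_energy is None:
            object.__setattr__(self, "k_ref_energy", float(e[0]))

    @classmethod
    def from_rows(cls, rows, **kwargs) -> "MaterialTable":
        """Build from an iterable of (energy, mu0, mu, gamma) rows."""
        arr = np.asarray(sorted(rows), dtype=float)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], **kwargs)

    @classmethod
    def from_csv(cls, path: Union[str, Path], **kwargs) -> "MaterialTable":
        """Read a material table from CSV.

        Expected header ``energy_keV,mu0_per_um,mu_per_um,gamma``;
        '#'-comment lines are skipped.
        """
        # strip '#' comments and blank lines first: genfromtxt would
        # otherwise take the header names from a leading comment line
        if hasattr(path, "read"):
            text = path.read()
        else:
            text = Path(path).read_text()
        lines = [
            ln for ln in text.splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        data = np.genfromtxt(io.StringIO("\n".join(lines)), delimiter=",", names=True)
        required = ("energy_keV", "mu0_per_um", "mu_per_um", "gamma")
        missing = [c for c in required if c not in (data.dtype.names or ())]
        if missing:
            raise ValueError(f"material CSV missing columns: {missing}")
        data = np.atleast_1d(data)
        return cls.from_rows(
            zip(data["energy_keV"], data["mu0_per_um"], data["mu_per_um"], data["gamma"]),
            **kwargs,
        )

    def _interp(self, column: np.ndarray, energy_keV: float) -> float:
        loge = np.log(self.energies)
        logv = np.log(column)
        x = np.log(energy_keV)
        if x <= loge[0]:
            i = 0
        elif x >= loge[-1]:
            i = len(loge) - 2
        else:
            i = int(np.searchsorted(loge, x) - 1)
        slope = (logv[i + 1] - logv[i]) / (loge[i + 1] - loge[i])
        return float(np.exp(logv[i] + slope * (x - loge[i])))

    def at(self, energy_keV: float) -> OpticalProperties:
        """Optical properties at ``energy_keV`` (log-log interpolated)."""
        energy_keV = float(energy_keV)
        if energy_keV <= 0:
            raise ValueError("photon energy must be positive")
        lo, hi = self.energies[0], self.energies[-1]
        if not (lo / 2 <= energy_keV <= 2 * hi):
            warnings.warn(
                f"energy {energy_keV} keV is far outside the tabulated span "
                f"[{lo}, {hi}] keV; power-law extrapolation may be unreliable",
                stacklevel=2,
            )
        # exact at tabulated points
        idx = np.nonzero(self.energies == energy_keV)[0]
        if idx.size:
            i = int(idx[0])
            mu0, mu, gamma = float(self.mu0[i]), float(self.mu[i]), float(self.gamma[i])
        else:
            mu0 = self._interp(self.mu0, energy_keV)
            mu = self._interp(self.mu, energy_keV)
            gamma = self._interp(self.gamma, energy_keV)
        k = self.k_ref * (self.k_ref_energy / energy_keV) ** self.p_k
        return OpticalProperties(mu0=mu0, mu=mu, gamma=gamma, k=k)

    @property
    def ref_energy(self) -> float:
        return float(self.k_ref_energy)


Material = Union[MaterialModel, MaterialTable]


def evaluate(material: Material, energy_keV: float) -> OpticalProperties:
    """Evaluate (mu0, mu, gamma, K) of ``material`` at ``energy_keV``."""
    return material.at(energy_keV)


def edge_transmission_min(material: Material, energy_keV: float, T_cm: float) -> float:
    """Minimal transmission q_min = exp[-(µT)_max] of the edge feature.

    ``T_cm`` is the feature thickness in cm.
    """
    if T_cm <= 0:
        raise ValueError("feature thickness must be positive")
    props = material.at(energy_keV)
    return float(np.exp(-props.mu * T_cm * UM_PER_CM))


def bulk_transmission(material: Material, energy_keV: float, T0_cm: float) -> float:
    """Transmission exp(-mu0*T0) through the bulk of the sample."""
    if T0_cm <= 0:
        raise ValueError("bulk thickness must be positive")
    props = material.at(energy_keV)
    return float(np.exp(-props.mu0 * T0_cm * UM_PER_CM))


def cm_contrast(material: Material, energy_keV: float) -> float:
    """Attenuation contrast C_m = (mu1 - mu0)/mu1 = mu/(mu0 + mu)."""
    props = material.at(energy_keV)
    mu1 = props.mu0 + props.mu
    if mu1 <= 0:
        raise ValueError("degenerate material: mu1 = mu0 + mu must be positive")
    return float(props.mu / mu1)
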