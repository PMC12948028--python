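"""Built-in parameter sets for a synchrotron breast-imaging beamline.

These reproduce the geometry and material parameters of existing and
prospective configurations for propagation-based imaging of breast
tissue at the Imaging and Medical Beamline (IMBL) of the Australian
Synchrotron: a 140 m source-to-detector distance, 400 µm source blur,
37.5 µm detector blur, an 8.6 cm bulk (adipose) sample containing a
0.5 cm glandular feature, and glandular/adipose optical constants at
26, 32 and 42 keV.
"""

from __future__ import annotations

from importlib import resources

from .forward_model import Sample
from .geometry import Geometry
from .materials import MaterialModel, MaterialTable

__all__ = [
    "imbl_geometry",
    "imbl_sample",
    "imbl_material_table",
    "imbl_material_model",
    "IMBL_REF_ENERGY_KEV",
]

#: anchor energy for the IMBL power-law material model and for K(λ, λ0)
IMBL_REF_ENERGY_KEV = 32.0


def imbl_geometry(M: float = 1.094, sigma_obj: float = 0.0) -> Geometry:
    """IMBL beamline geometry at a chosen magnification (default: the
    contrast-optimal 1.094)."""
    return Geometry(R=140.0, M=M, sigma_src=400.0, sigma_det=37.5, sigma_obj=sigma_obj)


def imbl_sample() -> Sample:
    """8.6 cm bulk with a 0.5 cm embedded feature."""
    return Sample(T0=8.60, T=0.50)


def imbl_material_table() -> MaterialTable:
    """Glandular-in-adipose breast-tissue optical constants at
    26/32/42 keV, log-log interpolated between rows."""
    with resources.files("pbiopt").joinpath("data/imbl_materials.csv").open() as fh:
        return MaterialTable.from_csv(fh, k_ref_energy=IMBL_REF_ENERGY_KEV)


def imbl_material_model() -> MaterialModel:
    """Power-law material model anchored at 32 keV (µ0 ∝ λ, µ ∝ λ³,
    γλ ∝ λ⁻¹, K ∝ λ²)."""
    return MaterialModel(
        ref_energy=IMBL_REF_ENERGY_KEV,
        mu0_ref=2.62e-5,
        mu_ref=8.50e-6,
        gamma_ref=869.0,
    )
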