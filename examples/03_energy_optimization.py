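"""Optimal X-ray energy from the transmission conditions.

The energy optimum of each metric reduces to a target transmission:
51% through the edge feature for contrast, 2% through the bulk for CNR
and 13.5% for the dose-normalized quality factors (under power-law
attenuation models anchored at 32 keV).  The magnification optimum is
energy-independent, so geometry and energy can be tuned separately.
"""

from pbiopt import bulk_transmission, edge_transmission_min, opt_e_transmission
from pbiopt.fixtures import imbl_material_model, imbl_sample

material = imbl_material_model()
sample = imbl_sample()

print(f"{'criterion':<10}{'E_opt (keV)':>12}   achieved transmission")
for criterion in ("contrast", "cnr", "q2d", "q3d"):
    opt = opt_e_transmission(material, sample, criterion)
    if criterion == "contrast":
        t = edge_transmission_min(material, opt.value, sample.T)
        where = "edge"
    else:
        t = bulk_transmission(material, opt.value, sample.T0)
        where = "bulk"
    print(f"{criterion:<10}{opt.value:>12.2f}   {t:.4f} through the {where}")

t32 = bulk_transmission(material, 32.0, sample.T0)
print()
print(f"bulk transmission at 32 keV: {t32:.3f}")
print("The contrast optimum sits at low energy (strong edge absorption),")
print("but barely any photons would cross 8.6 cm of tissue there; the")
print("noise- and dose-aware criteria move the optimum into the 30-40 keV")
print("band where roughly 10-15% of the beam reaches the detector.")
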