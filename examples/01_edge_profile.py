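"""Compute the near-Fresnel fluence profile across an embedded edge.

Builds the synchrotron breast-imaging configuration (140 m beamline,
400 µm source blur, 37.5 µm detector blur, 8.6 cm adipose bulk with a
0.5 cm glandular feature) at the contrast-optimal magnification and
32 keV, and prints the quantities that shape the profile.
"""

from pbiopt import contrast, contrast_from_profile, tie_hom_profile
from pbiopt.fixtures import imbl_geometry, imbl_material_table, imbl_sample

g = imbl_geometry(M=1.094)
material = imbl_material_table()
sample = imbl_sample()

profile = tie_hom_profile(g, material, energy_keV=32.0, sample=sample)

print(f"total edge blur sigma_M      : {profile.sigma_M:.2f} um")
print(f"phase-fringe gain gamma/N_F  : {profile.gain:.2f}")
print(f"near-Fresnel validity ratio  : {profile.validity_ratio:.2f}")
print(f"edge transmission q_min      : {profile.q_min:.4f}")
print(f"bright-side plateau fluence  : {profile.plateau:.4g} photons/um^2")

closed = contrast(g, material, 32.0, sample)
sampled = contrast_from_profile(profile)
print(f"propagation contrast (closed): {closed.value:.4f} "
      f"(absorption {closed.components['absorption']:.4f} "
      f"+ phase {closed.components['phase']:.4f})")
print(f"propagation contrast (fringe-sampled from the profile): {sampled:.4f}")
print()
print("The phase fringes carry ~6x more edge contrast than absorption alone;")
print("a validity ratio near 2 means this setup operates close to the edge")
print("of the near-Fresnel regime, so the fringe amplitude is near its cap.")
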