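"""Optimal geometric magnification under each image-quality metric.

For a fixed 140 m source-to-detector distance the best magnification
depends only on the detector-blur to source-blur ratio.  Each analytic
optimum (closed form or cubic root) is cross-checked by a numeric
argmax of the corresponding metric.
"""

from pbiopt import (
    Geometry, cnr, contrast, opt_m_cnr, opt_m_contrast, opt_m_q2d,
    opt_m_q3d, opt_m_resolution, opt_numeric, q2d, q3d, r2_at,
)
from pbiopt.fixtures import imbl_material_table, imbl_sample

S_SRC, S_DET, R = 400.0, 37.5, 140.0
material, sample = imbl_material_table(), imbl_sample()
g = lambda m: Geometry(R=R, M=m, sigma_src=S_SRC, sigma_det=S_DET)

metric_fns = {
    "contrast": lambda m: contrast(g(m), material, 32.0, sample).value,
    "cnr": lambda m: cnr(g(m), material, 32.0, sample).components["phase"],
    "q2d": lambda m: q2d(g(m), material, 32.0, sample).value,
    "q3d": lambda m: q3d(g(m), material, 32.0, sample, R_CT_cm=4.3).value,
}
analytic = {
    "resolution": opt_m_resolution(S_SRC, S_DET),
    "contrast": opt_m_contrast(S_SRC, S_DET),
    "cnr": opt_m_cnr(S_SRC, S_DET),
    "q2d": opt_m_q2d(S_SRC, S_DET),
    "q3d": opt_m_q3d(S_SRC, S_DET),
}

print(f"{'criterion':<12}{'M_opt':>8}{'R2 (m)':>9}{'numeric':>10}  method")
for name, opt in analytic.items():
    if name in metric_fns:
        num = opt_numeric(metric_fns[name], "magnification", (1.0005, 1.3))
        check = f"{num.value:8.4f}"
    else:
        check = "     (min of sigma_sys)"
    print(f"{name:<12}{opt.value:>8.4f}{r2_at(opt.value, R):>9.2f}{check:>10}  {opt.method}")

print()
print("Noise and dose push the optimum below the contrast value 1.094: the")
print("penumbral (source) blur costs noise performance that the detector")
print("blur does not, so CNR and the dose-normalized quality factors favor")
print("slightly shorter sample-to-detector distances.")
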