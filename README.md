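# pbiopt

Analytic modelling and design optimization of **propagation-based X-ray
phase-contrast imaging (PBI)** of a homogeneous edge feature embedded in
a uniform bulk sample — the standard "toy sample" for tuning
synchrotron and microfocus in-line imaging setups such as breast-CT
beamline configurations.

It is written for imaging physicists and beamline scientists who need to
answer, before an experiment: *at what geometric magnification, and at
what X-ray energy, does my setup deliver the best resolution, contrast,
contrast-to-noise ratio (CNR) or dose-normalized image quality?*

## The model

A sample of bulk thickness `T0` contains a thin edge feature of
thickness `T` whose refractive-index difference with the bulk is
monomorphous: `δ = γ·β` with a single ratio `γ` throughout
(the TIE-Hom assumption).  Imaged in a cone beam with total
source-to-detector distance `R`, magnification `M = (R1+R2)/R1`, and
Gaussian source/detector blurs `σ_src`, `σ_det`, the detected photon
fluence near the edge image is, in the near-Fresnel regime,

    I(x) = (η I_in e^{−μ0·T0} / M²) ·
           { e^{−(μT)max·E(x, σ_M)}  −  q·(γ/N_F)·(μT)max·x·G(x, σ_M) }

with `E` a cumulative Gaussian of width `σ_M` (system + intrinsic edge
blur), `G` a unit-area Gaussian, `q = e^{−(μT)max}` the minimal edge
transmission, and the phase-fringe gain `γ/N_F` controlled by the
minimal Fresnel number `N_F = 4π σ_M²/(λ R′)`, `R′ = R2/M`.

Sampling the first fringe pair at `x = ∓σ_M` gives the propagation
contrast

    C = (1 − q)/(1 + q) + (2πe)^{−1/2} q (γ/N_F)(μT)max ,

and multiplying by the Poisson per-resolution-element SNR gives the
CNR.  Dose-normalized 2D and 3D (CT) quality characteristics further
weight the CNR by spatial resolution and absorbed dose.  Every metric
factorizes into a geometry term (a function of `M` and the blur ratio
`r = σ_det/σ_src` alone) times an energy term, which yields closed-form
or one-dimensional-root optima:

| criterion    | optimal magnification                      | energy condition            |
|--------------|--------------------------------------------|-----------------------------|
| resolution   | `M = 1 + r²`                               | —                           |
| contrast     | `M = 1 + r`                                | edge transmission `e^{−2/3}` (51%) |
| CNR          | `r = (M−1)(2M−1)^{1/2}`                    | bulk transmission `e^{−4}` (2%)    |
| Q (2D)       | `M = 1 + r/√2`                             | bulk transmission `e^{−2}` (13.5%) |
| Q (3D, CT)   | `r = (M−1)[(4M+1)/(3M−1)]^{1/2}`           | bulk transmission `e^{−2}` (13.5%) |

A Monte-Carlo module draws Poisson-noisy detector images from the
analytic profile and verifies the contrast/CNR statistics empirically.

## Worked example

The packaged fixture models a 140 m synchrotron beamline imaging an
8.6 cm breast-tissue sample (glandular feature in adipose bulk, optical
constants tabulated at 26/32/42 keV) with `σ_src = 400 µm` and
`σ_det = 37.5 µm`:

```python
from pbiopt import contrast, tie_hom_profile, opt_m_cnr, r2_at
from pbiopt.fixtures import imbl_geometry, imbl_material_table, imbl_sample

g = imbl_geometry(M=1.094)          # contrast-optimal magnification
mat, sample = imbl_material_table(), imbl_sample()

profile = tie_hom_profile(g, mat, energy_keV=32.0, sample=sample)
print(profile.sigma_M, profile.gain)          # 48.54 um, 12.50
c = contrast(g, mat, 32.0, sample)
print(c.value, c.components)                  # 0.1445 = 0.0212 abs + 0.1232 phase

m = opt_m_cnr(400.0, 37.5)                    # CNR-optimal magnification
print(m.value, r2_at(m.value, 140.0))         # 1.0866, R2 = 11.15 m
```

Running `python examples/02_optimal_magnification.py` prints the full
design table:

```
criterion      M_opt   R2 (m)   numeric  method
resolution    1.0088     1.22     (min of sigma_sys)  closed_form
contrast      1.0938    12.00    1.0938  closed_form
cnr           1.0866    11.15    1.0866  cubic_root
q2d           1.0663     8.70    1.0663  closed_form
q3d           1.0605     7.98    1.0605  cubic_root
```

Read it as: the sharpest images come at near-contact geometry
(`R2 ≈ 1.2 m`), the strongest fringes at `R2 ≈ 12 m`, and once photon
noise and radiation dose are accounted for the best operating points
move down to `R2 ≈ 8–11 m`.  The numeric column is an independent
grid/golden-section argmax of each metric confirming the analytic
optimum.  The other examples print the edge profile, the
transmission-condition energy optima, and a seeded Monte-Carlo
verification of the contrast/CNR statistics.

A thin CLI mirrors the library: `pbiopt summary`, `pbiopt profile`,
`pbiopt scan`, `pbiopt optimize --criterion cnr`, `pbiopt simulate`,
configured by TOML files (see `pbiopt --help`).

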