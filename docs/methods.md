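# Methods

## Model and assumptions

`pbiopt` models in-line (propagation-based) X-ray imaging of a
one-dimensional edge feature embedded in a uniform bulk slab, in the
near-Fresnel regime where the transport-of-intensity equation for a
homogeneous ("monomorphous", δ = γβ) object applies.  The assumptions
inherited from that regime:

- **Thin sample**: the feature's axial position inside the bulk is
  irrelevant; transmission factorizes into bulk × feature terms.
- **Gaussian optics**: source intensity distribution, detector LSF and
  the intrinsic edge unsharpness are Gaussian, so blurs combine by
  adding variances.  The system LSF referred to the object plane is
  `σ_sys(M) = [(M−1)²σ_src² + σ_det²]^{1/2}/M`.
- **Monochromatic beam**, LSF independent of energy, incident fluence
  uniform near the feature.
- **Near-Fresnel validity**: the expansion holds while
  `N_F ≫ (μT)max·γ`.  The package computes the ratio
  `N_F/[(μT)max·γ]` on every profile and metric and flags values below
  10 (`validity_ok` in `MetricResult.inputs_echo`), but reports the
  raw numbers unclipped — the analytic optima do not depend on the
  flag, and clipping would silently distort comparisons.
- **Poisson counting statistics** for all noise quantities.

Profiles and coordinates live in the object plane; detector-plane
positions are `M·x`, and the detected fluence carries the `1/M²`
magnification dilution (this is what makes SNR ∝ 1/M and produces the
published CNR optimum).

## Conventions with a free constant

Several printed results fix otherwise arbitrary conventions; the
package adopts the unique choices that make them mutually consistent:

- **Equivalent width** `Δ = (2π)^{1/2}σ`.  Only ratios of widths enter
  any optimum, so this is benign, but it is the constant under which
  the absorption/phase constants `a0 = (1−e^{−2/3})/(1+e^{−2/3})` and
  `c0 = (2/3)e^{−2/3}(2πe)^{−1/2}` come out as printed.
- **Fresnel number** `N_F = 4π σ_M²/(λR′)`, fixed by requiring the
  fringe term `(γ/N_F)(μT)max·x·G(x, σ_M)` to equal the TIE-Hom
  second-derivative term with `a² = γR′λ/(4π)`.  The fringe amplitude
  bound `|xG| ≤ (2πe)^{−1/2}` then caps the phase contrast exactly as
  the validity condition demands.
- **Fringe attenuation** `q_eff`: the fringe amplitude is multiplied by
  the minimal edge transmission `q_min = e^{−(μT)max}`.  This is the
  only convention consistent with the optimized-contrast constant `c0`;
  `tie_hom_profile` exposes the alternatives (`"one"`, `"local"`) for
  comparison.
- **Noise-collection area** `A_n = 2πσ_det²` (the detector PSF
  equivalent area).  Any M-independent constant yields the same CNR
  optimum; the PSF area makes the absolute SNR physically
  interpretable.
- **Absolute normalization of Q factors**: internal convention
  (κ = κ3 = 1, λ in Å, R in m, σ in µm).  Only argmax locations,
  ratios and scaling laws are meaningful; absolute Q values are not
  comparable across conventions.
- **Energy/wavelength conversion**: hc = 12.3984198 keV·Å.  Internal
  length unit µm; thicknesses accepted in cm, distances in m.

## Materials

Two material representations stand behind every metric:

- `MaterialModel`: power laws around an anchor energy — `μ ∝ λ³`
  (feature contrast), `μ0 ∝ λ` (bulk; empirically near-linear for soft
  tissue in the 20–40 keV band, with a quadratic alternative selectable
  via `p_mu0=2`), `γλ ∝ λ⁻¹` (so `γ ∝ λ⁻²`), and dose-conversion
  coefficient `K ∝ λ²`.  All exponents are user-overridable.
- `MaterialTable`: tabulated `(E, μ0, μ, γ)` rows, log–log linear
  between rows (a local power law) and extrapolated with the nearest
  segment's slope, warning beyond `[Emin/2, 2·Emax]`.  Tabulated
  energies reproduce their rows exactly.  `K` has no tabulated column
  and follows the λ² law anchored at a settable reference (32 keV in
  the packaged fixture).

The packaged fixture is a glandular-in-adipose breast-tissue pair at
26/32/42 keV on a 140 m beamline.  Three anchor rows cannot reproduce
energy optima that depend on full attenuation databases; energy-axis
results with the table material are therefore asserted as bands (the
3D-quality optimum lies in 30–36 keV), while the transmission-condition
optima (exact constants `e^{−2/3}`, `e^{−4}`, `e^{−2}`, not their
rounded 51%/2%/13.5% forms) are solved on the power-law model, where
they are sharp.

## Optimization

Magnification optima use the closed forms where they exist and
bracketed Brent root-finding on the monotone look-up forms
`r = (M−1)(2M−1)^{1/2}` (CNR) and `r = (M−1)[(4M+1)/(3M−1)]^{1/2}`
(3D quality) otherwise — Cardano's formula is avoided deliberately.
Residuals are below 1e−12; the solvers are exact inverses of the
look-up curves (round-trip < 1e−10).

The numeric cross-checker (`opt_numeric`) runs a 512-point coarse grid
followed by bounded golden-section refinement (tolerance 1e−4 in M,
0.05 keV in E), falling back to the grid maximum with a warning when
the coarse scan shows multimodality.

Two subtleties:

- The analytic CNR optimum maximizes the **phase-contrast part** of the
  CNR.  The full CNR adds the M-independent absorption contrast times
  SNR ∝ 1/M, which pulls its peak ~1.5e−3 below the cubic root on the
  beamline blur ratio; numeric cross-checks therefore target the phase
  component (exposed in `MetricResult.components`), and the package
  asserts the full-CNR peak sits below the cubic root.
- The 3D quality factor is optimized in analytic mode with the slowly
  varying correction `f(M, λ) ≡ 1`; a numerical treatment including it
  would move the optimum slightly lower.  A user-pluggable `f_corr`
  hook exists, but no default correction is shipped because its closed
  form is a separate modelling choice.

The 2D-quality geometric factor is implemented as
`G2(M) = R(M−1)/[(M−1)²σ_src² + σ_det²]^{3/2}`, the unique separable
geometry factor whose maximum is `M = 1 + σ_det/(√2 σ_src)`.

## Monte-Carlo verification

`simulate_edge_image` draws independent Poisson counts per detector
pixel with expectation `fluence(x_j)·pitch²`, columns mapped through
the magnification.  The RNG is numpy's seeded PCG64 generator
(bit-reproducible across platforms); the generator identity is recorded
on the image.

`estimate_contrast_cnr` estimates the fringe contrast from
column-averaged counts **linearly interpolated at x = ∓σ_M** — the same
definition as the noiseless `contrast_from_profile` — rather than from
the nearest pixel centres: nearest-pixel sampling carries an O(pitch)
discretization bias that would dominate the bootstrap standard error
for tall images, turning a statistical comparison into a systematic
one.  The CNR multiplies the contrast by the square root of the mean
counts over the feature-side plateau (x > 4σ_M, whose transmission is
the one entering the analytic SNR) scaled to the PSF noise-collection
area.  Standard errors come from 200 row-resampling bootstrap
replicates.

The verification runs use a 2.5 µm pixel pitch (≈ σ_M/20).  The pitch
is a discretization parameter of the numerical experiment, not a
physical datum of the modelled setup (37.5 µm is the detector's blur
σ, not its sampling pitch); it is chosen fine enough that the sampled
profile resolves the fringe and the residual interpolation bias is
well below one standard error.  Stochastic tests compare at the 3-SE
level with fixed seeds; image sizes (10⁴ rows) keep each run in the
low seconds.

## What the synthetic data does and does not show

The Poisson image generator emulates ideal photon counting on the
analytic near-Fresnel profile.  It shares every idealization of the
model: no detector read-out noise or pixel cross-talk beyond the
Gaussian LSF, no beam hardening or polychromatic blur, no scattering,
no phase-retrieval step, and a strictly one-dimensional edge.  Passing
tests therefore demonstrate internal consistency of the analytic
contrast/CNR with Poisson statistics — not that a physical detector
would realize these numbers.  Likewise, the energy optima inherit the
crudeness of the power-law attenuation models; for a real design they
should be re-evaluated with tabulated attenuation and dose data via
`MaterialTable`.

## Degenerate inputs and numerical choices

- `M = 1` (contact): no propagation; the Fresnel number is reported as
  +∞ with a warning and all phase terms vanish.
- `σ_obj = 0` (sharp edge): the cumulative-Gaussian edge becomes a
  Heaviside step (0 at x ≤ 0 by convention).
- Negative fluence (validity grossly violated): profiles warn and
  return unclipped values; the simulator refuses to draw counts.
- Default profile grid: 4096 points over ±8σ_M; plateaus match their
  closed forms to 1e−10 relative.
- Scan CSVs use fixed `%.10g` formatting so repeated runs are
  byte-identical.

## Known limitations

Absolute Q values are convention-bound; polychromatic spectra,
absorption edges, 2D features, full Fresnel propagation beyond the TIE
regime, and dose in gray from real mass energy-absorption tables are
out of scope.  The edge-transmission contrast condition favours strong
feature absorption and is physically unrealistic for thick samples —
the CNR/quality conditions are the ones meant for design use.
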