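import math

import numpy as np
import pytest

from pbiopt import optimize
from pbiopt.forward_model import Sample, tie_hom_profile
from pbiopt.geometry import Geometry
from pbiopt.materials import MaterialModel, UM_PER_CM
from pbiopt.metrics import (
    cnr,
    constants,
    contrast,
    contrast_from_profile,
    q2d,
    q3d,
    snr,
)


def imbl(M):
    return Geometry(R=140.0, M=M, sigma_src=400.0, sigma_det=37.5)


class TestContrast:
    def test_showcase_value_and_split(self, imbl_table, imbl_sample):
        # frozen oracle: (1-q)/(1+q) = 0.021247, phase = 0.123233
        res = contrast(imbl(1.094), imbl_table, 32.0, imbl_sample)
        assert res.components["absorption"] == pytest.approx(0.021247, abs=2e-6)
        assert res.components["phase"] == pytest.approx(0.123233, abs=2e-6)
        assert res.value == pytest.approx(0.144479, abs=3e-6)

    def test_contact_image_is_pure_absorption(self, imbl_table, imbl_sample):
        res = contrast(imbl(1.0), imbl_table, 32.0, imbl_sample)
        q = math.exp(-0.0425)
        assert res.components["phase"] == 0.0
        assert res.value == pytest.approx((1 - q) / (1 + q), rel=1e-12)

    def test_absorption_addend_at_optimal_edge_transmission(self):
        # (µT)_max = 2/3 gives the a0 constant
        mat = MaterialModel(ref_energy=32.0, mu0_ref=1e-5,
                            mu_ref=(2.0 / 3.0) / (0.5 * UM_PER_CM), gamma_ref=800.0)
        res = contrast(imbl(1.0), mat, 32.0, Sample(T0=8.6, T=0.5))
        a0, _ = constants()
        assert res.components["absorption"] == pytest.approx(a0, rel=1e-12)
        assert a0 == pytest.approx(0.322, abs=5e-4)

    def test_validity_flag_travels_with_result(self, imbl_table, imbl_sample):
        res = contrast(imbl(1.094), imbl_table, 32.0, imbl_sample)
        assert res.inputs_echo["validity_ratio"] == pytest.approx(1.8818, abs=2e-4)
        assert res.inputs_echo["validity_ok"] is False


class TestContrastFromProfile:
    def test_flat_profile_gives_zero(self, imbl_table, imbl_sample):
        p = tie_hom_profile(imbl(1.094), imbl_table, 32.0, imbl_sample)
        flat = type(p)(
            x=p.x, fluence=np.full_like(p.fluence, 3.0),
            absorption_part=p.absorption_part, phase_part=p.phase_part,
            sigma_M=p.sigma_M, gain=p.gain, validity_ratio=p.validity_ratio,
            q_min=p.q_min, plateau=p.plateau, magnification=p.magnification,
            energy_keV=p.energy_keV,
        )
        assert contrast_from_profile(flat) == 0.0

    def test_agrees_with_closed_form_on_showcase(self, imbl_table, imbl_sample):
        # the closed form uses plateau approximations at ±sigma_M; on the
        # IMBL showcase the two definitions differ by ~3% (frozen bound)
        p = tie_hom_profile(imbl(1.094), imbl_table, 32.0, imbl_sample)
        sampled = contrast_from_profile(p)
        closed = contrast(imbl(1.094), imbl_table, 32.0, imbl_sample).value
        assert sampled == pytest.approx(0.140372, abs=2e-6)  # frozen oracle
        assert abs(sampled - closed) / closed < 0.15

    def test_pure_absorption_profile_approximation_ratio(self, imbl_sample):
        # with no phase contrast the fringe-sampled value approaches
        # (1-q)/(1+q) times the cumulative-Gaussian sampling factor
        # (Phi(1) - Phi(-1)) ≈ 0.6827 for weak absorption
        mat = MaterialModel(ref_energy=32.0, mu0_ref=2.62e-5, mu_ref=8.5e-6,
                            gamma_ref=800.0)
        p = tie_hom_profile(imbl(1.0), mat, 32.0, imbl_sample)
        q = p.q_min
        sampled = contrast_from_profile(p)
        closed = (1 - q) / (1 + q)
        assert sampled / closed == pytest.approx(0.6827, abs=0.01)

    def test_zero_profile_rejected(self, imbl_table, imbl_sample):
        p = tie_hom_profile(imbl(1.094), imbl_table, 32.0, imbl_sample, I_in=0.0)
        with pytest.raises(ValueError):
            contrast_from_profile(p)


class TestSnrCnr:
    def test_snr_frozen_oracle(self, imbl_table, imbl_sample):
        # [2π·37.5²·exp(−2.2532 − 0.0425)]^½ / 1.087
        val = snr(imbl(1.087), imbl_table, 32.0, imbl_sample, I_in=1.0, eta=1.0)
        assert val == pytest.approx(27.4402, abs=2e-3)

    def test_snr_square_root_fluence_law(self, imbl_table, imbl_sample):
        base = snr(imbl(1.087), imbl_table, 32.0, imbl_sample, I_in=1.0)
        assert snr(imbl(1.087), imbl_table, 32.0, imbl_sample, I_in=4.0) == pytest.approx(
            2.0 * base, rel=1e-12
        )
        assert snr(imbl(1.087), imbl_table, 32.0, imbl_sample, I_in=0.0) == 0.0

    def test_cnr_is_contrast_times_snr(self, imbl_table, imbl_sample):
        g = imbl(1.087)
        res = cnr(g, imbl_table, 32.0, imbl_sample, I_in=1e3)
        c = contrast(g, imbl_table, 32.0, imbl_sample)
        s = snr(g, imbl_table, 32.0, imbl_sample, I_in=1e3)
        assert res.value == pytest.approx(c.value * s, rel=1e-12)
        assert res.components["phase"] == pytest.approx(c.components["phase"] * s, rel=1e-12)

    def test_cnr_zero_without_photons(self, imbl_table, imbl_sample):
        assert cnr(imbl(1.087), imbl_table, 32.0, imbl_sample, I_in=0.0).value == 0.0

    def test_cnr_phase_part_linear_in_distance(self, imbl_table, imbl_sample):
        g1 = imbl(1.087)
        g2 = Geometry(R=280.0, M=1.087, sigma_src=400.0, sigma_det=37.5)
        p1 = cnr(g1, imbl_table, 32.0, imbl_sample).components["phase"]
        p2 = cnr(g2, imbl_table, 32.0, imbl_sample).components["phase"]
        assert p2 == pytest.approx(2.0 * p1, rel=1e-12)

    def test_cnr_phase_argmax_matches_cubic(self, imbl_table, imbl_sample):
        fn = lambda m: cnr(imbl(m), imbl_table, 32.0, imbl_sample).components["phase"]
        opt = optimize.opt_numeric(fn, "magnification", (1.001, 1.3))
        assert opt.value == pytest.approx(optimize.opt_m_cnr(400.0, 37.5).value, abs=1e-3)

    def test_full_cnr_peaks_below_phase_only_optimum(self, imbl_table, imbl_sample):
        # the M-independent absorption addend times SNR ∝ 1/M pulls the
        # peak slightly below the phase-part cubic root
        fn = lambda m: cnr(imbl(m), imbl_table, 32.0, imbl_sample).value
        opt = optimize.opt_numeric(fn, "magnification", (1.001, 1.3))
        assert 1.0 < opt.value < optimize.opt_m_cnr(400.0, 37.5).value


class TestQualityFactors:
    def test_vanish_at_contact(self, imbl_table, imbl_sample):
        assert q2d(imbl(1.0), imbl_table, 32.0, imbl_sample).value == 0.0
        assert q3d(imbl(1.0), imbl_table, 32.0, imbl_sample, 4.3).value == 0.0

    @pytest.mark.parametrize("energy", [26.0, 32.0, 42.0])
    def test_q2d_argmax_independent_of_energy(self, energy, imbl_table, imbl_sample):
        fn = lambda m: q2d(imbl(m), imbl_table, energy, imbl_sample).value
        opt = optimize.opt_numeric(fn, "magnification", (1.001, 1.3))
        assert opt.value == pytest.approx(1.0663, abs=1e-3)

    def test_q2d_linear_in_total_distance(self, imbl_table, imbl_sample):
        g1 = imbl(1.066)
        g2 = Geometry(R=280.0, M=1.066, sigma_src=400.0, sigma_det=37.5)
        assert q2d(g2, imbl_table, 32.0, imbl_sample).value == pytest.approx(
            2.0 * q2d(g1, imbl_table, 32.0, imbl_sample).value, rel=1e-12
        )

    def test_q3d_argmax_analytic_mode(self, imbl_table, imbl_sample):
        fn = lambda m: q3d(imbl(m), imbl_table, 32.0, imbl_sample, 4.3).value
        opt = optimize.opt_numeric(fn, "magnification", (1.001, 1.3))
        assert opt.value == pytest.approx(1.0605, abs=1e-3)

    def test_q3d_energy_argmax_in_showcase_band(self, imbl_table, imbl_sample):
        fn = lambda e: q3d(imbl(1.06), imbl_table, e, imbl_sample, 4.3).value
        opt = optimize.opt_numeric(fn, "energy", (20.0, 42.0))
        assert 30.0 <= opt.value <= 36.0

    def test_q3d_correction_hook(self, imbl_table, imbl_sample):
        base = q3d(imbl(1.06), imbl_table, 32.0, imbl_sample, 4.3).value
        scaled = q3d(imbl(1.06), imbl_table, 32.0, imbl_sample, 4.3,
                     f_corr=lambda m, e: 0.5).value
        assert scaled == pytest.approx(0.5 * base, rel=1e-12)


def test_analytic_constants():
    a0, c0 = constants()
    e23 = math.exp(-2.0 / 3.0)
    assert a0 == pytest.approx((1 - e23) / (1 + e23), rel=1e-15)
    assert c0 == pytest.approx((2.0 / 3.0) * e23 / math.sqrt(2 * math.pi * math.e),
                               rel=1e-15)
    assert round(a0, 3) == 0.322
    assert round(c0, 3) == 0.083


@pytest.mark.parametrize("ratio", [0.05, 0.09375, 0.25, 0.5, 1.0, 2.0])
def test_metric_ordering_across_blur_ratios(ratio, imbl_table, imbl_sample):
    # noise breaks the source/detector symmetry: CNR and Q optima always
    # sit below the contrast optimum
    s_src = 400.0
    s_det = ratio * s_src
    m_c = optimize.opt_m_contrast(s_src, s_det).value
    assert optimize.opt_m_cnr(s_src, s_det).value < m_c
    assert optimize.opt_m_q3d(s_src, s_det).value < m_c
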