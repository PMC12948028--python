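import json
import math

import numpy as np
import pytest
from scipy import stats

from pbiopt.forward_model import (
    XG_MAX,
    Sample,
    edge_shape,
    tie_hom_profile,
    validity_ratio,
)
from pbiopt.geometry import Geometry, sigma_M
from pbiopt.materials import MaterialModel, UM_PER_CM


class TestEdgeShape:
    def test_half_at_origin_and_limits(self):
        assert edge_shape(0.0, 10.0) == 0.5
        assert edge_shape(1e6, 10.0) == pytest.approx(1.0, abs=1e-15)
        assert edge_shape(-1e6, 10.0) == pytest.approx(0.0, abs=1e-15)

    def test_matches_normal_cdf_at_one_sigma(self):
        assert edge_shape(10.0, 10.0) == pytest.approx(stats.norm.cdf(1.0), rel=1e-12)

    def test_sharp_edge_is_heaviside(self):
        x = np.array([-1.0, 0.0, 1e-12, 1.0])
        np.testing.assert_array_equal(edge_shape(x, 0.0), [0.0, 0.0, 1.0, 1.0])


def test_fringe_bound_constant():
    # max |x G(x, sigma)| = (2 pi e)^(-1/2), attained at x = ±sigma
    sigma = 48.5
    x = np.linspace(-6 * sigma, 6 * sigma, 200001)
    xg = x * np.exp(-(x**2) / (2 * sigma**2)) / (math.sqrt(2 * math.pi) * sigma)
    assert np.max(np.abs(xg)) == pytest.approx(XG_MAX, rel=1e-8)
    assert XG_MAX == pytest.approx(0.2420, abs=5e-5)


class TestTieHomProfile:
    def test_plateaus_match_closed_forms(self, imbl_geometry, imbl_table, imbl_sample):
        p = tie_hom_profile(imbl_geometry, imbl_table, 32.0, imbl_sample,
                            I_in=2.0, eta=0.7)
        props = imbl_table.at(32.0)
        plateau = 0.7 * 2.0 * math.exp(-props.mu0 * 8.6e4) / imbl_geometry.M**2
        assert p.fluence[0] == pytest.approx(plateau, rel=1e-10)
        assert p.fluence[-1] == pytest.approx(plateau * p.q_min, rel=1e-10)

    def test_absorption_part_is_blurred_edge(self, imbl_geometry, imbl_table, imbl_sample):
        p = tie_hom_profile(imbl_geometry, imbl_table, 32.0, imbl_sample)
        mu_t = imbl_table.at(32.0).mu * imbl_sample.T * UM_PER_CM
        expected = np.exp(-mu_t * edge_shape(p.x, p.sigma_M))
        np.testing.assert_allclose(p.absorption_part, expected, rtol=1e-13)

    def test_phase_part_is_antisymmetric(self, imbl_geometry, imbl_table, imbl_sample):
        p = tie_hom_profile(imbl_geometry, imbl_table, 32.0, imbl_sample)
        np.testing.assert_allclose(p.phase_part, -p.phase_part[::-1], atol=1e-16)
        # odd integrand: quadrature over the symmetric grid vanishes
        assert np.trapezoid(p.phase_part, p.x) == pytest.approx(0.0, abs=1e-12)

    def test_bright_fringe_on_low_absorption_side(self, imbl_geometry, imbl_table, imbl_sample):
        p = tie_hom_profile(imbl_geometry, imbl_table, 32.0, imbl_sample)
        assert np.all(p.phase_part[p.x < 0] > 0)
        assert np.all(p.phase_part[p.x > 0] < 0)

    def test_fringes_enhance_edge_visibility(self, imbl_geometry, imbl_table, imbl_sample):
        p = tie_hom_profile(imbl_geometry, imbl_table, 32.0, imbl_sample)
        s = p.sigma_M
        step = lambda f: np.interp(-s, p.x, f) - np.interp(s, p.x, f)
        assert step(p.fluence) > step(p.plateau * p.absorption_part)

    def test_phase_part_linear_in_total_distance(self, imbl_table, imbl_sample):
        g1 = Geometry(R=140.0, M=1.094, sigma_src=400.0, sigma_det=37.5)
        g2 = Geometry(R=280.0, M=1.094, sigma_src=400.0, sigma_det=37.5)
        x = np.linspace(-300, 300, 501)
        p1 = tie_hom_profile(g1, imbl_table, 32.0, imbl_sample, x_grid=x)
        p2 = tie_hom_profile(g2, imbl_table, 32.0, imbl_sample, x_grid=x)
        np.testing.assert_allclose(p2.phase_part, 2.0 * p1.phase_part, rtol=1e-12)

    def test_contact_image_has_no_fringes(self, imbl_table, imbl_sample):
        g = Geometry(R=140.0, M=1.0, sigma_src=400.0, sigma_det=37.5)
        p = tie_hom_profile(g, imbl_table, 32.0, imbl_sample)
        np.testing.assert_array_equal(p.phase_part, 0.0)
        assert p.gain == 0.0

    def test_only_total_blur_enters(self, imbl_table, imbl_sample):
        # a profile with intrinsic edge blur equals one with the system
        # blur inflated to the same sigma_M
        M = 1.094
        g_obj = Geometry(R=140.0, M=M, sigma_src=400.0, sigma_det=37.5,
                         sigma_obj=30.0)
        target = sigma_M(g_obj)
        s_det = math.sqrt((M * target) ** 2 - ((M - 1) * 400.0) ** 2)
        g_sys = Geometry(R=140.0, M=M, sigma_src=400.0, sigma_det=s_det)
        assert sigma_M(g_sys) == pytest.approx(target, rel=1e-14)
        x = np.linspace(-400, 400, 801)
        p_obj = tie_hom_profile(g_obj, imbl_table, 32.0, imbl_sample, x_grid=x)
        p_sys = tie_hom_profile(g_sys, imbl_table, 32.0, imbl_sample, x_grid=x)
        np.testing.assert_allclose(p_obj.fluence, p_sys.fluence, rtol=1e-12)

    def test_negative_fluence_warns_not_clips(self, imbl_sample):
        # an extreme gain (huge gamma, long distance) breaks validity
        strong = MaterialModel(ref_energy=32.0, mu0_ref=2.62e-5, mu_ref=8.5e-6,
                               gamma_ref=5e5)
        g = Geometry(R=1000.0, M=1.5, sigma_src=400.0, sigma_det=37.5)
        with pytest.warns(UserWarning, match="validity"):
            p = tie_hom_profile(g, strong, 32.0, imbl_sample)
        assert np.any(p.fluence < 0)

    def test_csv_export_with_sidecar(self, tmp_path, imbl_geometry, imbl_table, imbl_sample):
        p = tie_hom_profile(imbl_geometry, imbl_table, 32.0, imbl_sample,
                            n_points=64)
        out = tmp_path / "profile.csv"
        p.to_csv(out)
        data = np.genfromtxt(out, delimiter=",", names=True)
        np.testing.assert_allclose(data["x_um"], p.x, rtol=1e-9)
        np.testing.assert_allclose(data["fluence_per_um2"], p.fluence, rtol=1e-9)
        meta = json.loads((tmp_path / "profile.csv.json").read_text())
        assert meta["sigma_M_um"] == pytest.approx(p.sigma_M)
        assert meta["validity_ratio"] == pytest.approx(p.validity_ratio)


class TestValidityRatio:
    def test_imbl_showcase_operates_near_boundary(self, imbl_geometry, imbl_table):
        # frozen from direct evaluation: 69.5006 / (0.0425 · 869)
        assert validity_ratio(imbl_geometry, imbl_table, 32.0, 0.50) == pytest.approx(
            1.8818, abs=2e-4
        )

    def test_halving_defocus_doubles_ratio(self, imbl_table):
        g1 = Geometry(R=140.0, M=1.094, sigma_src=400.0, sigma_det=37.5)
        g2 = Geometry(R=70.0, M=1.094, sigma_src=400.0, sigma_det=37.5)
        r1 = validity_ratio(g1, imbl_table, 32.0, 0.50)
        r2 = validity_ratio(g2, imbl_table, 32.0, 0.50)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-12)
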