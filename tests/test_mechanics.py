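"""Beam-model tests: closed-form oracles, equilibrium invariants, inverse solve."""

import numpy as np
import pytest

import whiskerglm as wg
from whiskerglm.mechanics import ContactLost


@pytest.fixture(scope="module")
def cylinder():
    """Uniform cylindrical beam with closed-form cantilever behavior."""
    return wg.WhiskerGeometry(
        length_mm=20.0, base_radius_um=100.0, tip_radius_um=100.0,
        youngs_modulus_pa=3e9, n_nodes=200,
    )


class TestSecondMoment:
    def test_uniform_cylinder_closed_form(self, cylinder):
        expected = np.pi * 0.1**4 / 4
        for s in [0.0, 5.0, 20.0]:
            assert wg.second_moment(cylinder, s) == pytest.approx(expected, rel=1e-12)

    def test_base_value_tapered(self, geometry):
        assert wg.second_moment(geometry, 0.0) == pytest.approx(np.pi * 0.07**4 / 4, rel=1e-12)

    def test_non_increasing_along_taper(self, geometry):
        s = np.linspace(0, geometry.length_mm, 50)
        i = wg.second_moment(geometry, s)
        assert np.all(np.diff(i) <= 0)

    def test_domain_error(self, geometry):
        with pytest.raises(ValueError):
            wg.second_moment(geometry, -1.0)
        with pytest.raises(ValueError):
            wg.second_moment(geometry, geometry.length_mm + 1.0)


class TestForwardSolver:
    def test_small_deflection_matches_cantilever_closed_form(self, cylinder):
        # point constraint displacing the beam by 0.1 mm at a = 10 mm:
        # delta = F a^3 / (3 E I), base moment = F a
        a_m, delta_m = 0.010, 0.1e-3
        ei = 3e9 * np.pi * (100e-6) ** 4 / 4
        f_expected = 3 * ei * delta_m / a_m**3 * 1e6          # uN
        m_expected = f_expected * a_m                          # uN*m
        res = wg.deflect_whisker(cylinder, wg.ContactConstraint((10.0, 0.1)))
        assert np.hypot(*res.force_uN) == pytest.approx(f_expected, rel=0.02)
        assert res.reactions.m_uNm == pytest.approx(m_expected, rel=0.02)

    def test_constraint_on_rest_whisker_is_null(self, geometry):
        res = wg.deflect_whisker(geometry, wg.ContactConstraint((12.0, 0.0)))
        assert res.reactions.as_array().tolist() == [0.0, 0.0, 0.0]
        np.testing.assert_array_equal(res.shape_mm, geometry.undeflected_nodes_mm())

    def test_force_perpendicular_to_tangent(self, geometry, contact_tangent):
        for point in [(15.0, 2.0), (10.0, -1.0), (20.0, 3.0)]:
            res = wg.deflect_whisker(geometry, wg.ContactConstraint(point))
            t_hat = contact_tangent(res, geometry)
            f_hat = res.force_uN / np.hypot(*res.force_uN)
            assert abs(np.dot(f_hat, t_hat)) < 1e-6

    def test_static_equilibrium_moment_is_lever_cross_force(self, geometry):
        res = wg.deflect_whisker(geometry, wg.ContactConstraint((15.0, 2.0)))
        ds = geometry.ds_mm
        k = int(res.contact_arc_mm / ds)
        frac = res.contact_arc_mm / ds - k
        p_c = (1 - frac) * res.shape_mm[k] + frac * res.shape_mm[k + 1]  # mm
        m = (p_c[0] * res.force_uN[1] - p_c[1] * res.force_uN[0]) * 1e-3  # uN*m
        assert res.reactions.m_uNm == pytest.approx(m, rel=1e-6)
        # reported Fx is the -x component of the applied force, Fy the +y one
        assert res.reactions.fx_uN == pytest.approx(-res.force_uN[0])
        assert res.reactions.fy_uN == pytest.approx(res.force_uN[1])

    def test_small_deflection_linearity(self, geometry):
        r1 = wg.deflect_whisker(geometry, wg.ContactConstraint((15.0, 0.05)))
        r2 = wg.deflect_whisker(geometry, wg.ContactConstraint((15.0, 0.10)))
        assert r2.reactions.fy_uN == pytest.approx(2 * r1.reactions.fy_uN, rel=0.05)
        assert r2.reactions.m_uNm == pytest.approx(2 * r1.reactions.m_uNm, rel=0.05)
        # the axial component is second order in the deflection
        assert abs(r1.reactions.fx_uN) < 0.05 * abs(r1.reactions.fy_uN)

    def test_mesh_convergence(self, geometry):
        fine = wg.WhiskerGeometry(n_nodes=2 * geometry.n_nodes)
        ra = wg.deflect_whisker(geometry, wg.ContactConstraint((15.0, 2.0))).reactions.as_array()
        rb = wg.deflect_whisker(fine, wg.ContactConstraint((15.0, 2.0))).reactions.as_array()
        assert np.all(np.abs(rb - ra) / np.abs(ra) < 0.005)

    def test_unreachable_constraint(self, geometry):
        with pytest.raises(ContactLost):
            wg.deflect_whisker(geometry, wg.ContactConstraint((30.0, 10.0)))

    def test_slip_off_near_tip(self, geometry):
        # a large push very close to the tip has no contact equilibrium
        with pytest.raises(ContactLost):
            wg.deflect_whisker(geometry, wg.ContactConstraint((22.5, 4.0)))


class TestInverseSolver:
    @pytest.mark.parametrize("point", [(15.0, 2.0), (10.0, 1.0), (12.0, -1.5)])
    def test_roundtrip_within_one_percent(self, geometry, point):
        fw = wg.deflect_whisker(geometry, wg.ContactConstraint(point))
        ds = geometry.ds_mm
        k = int(fw.contact_arc_mm / ds)
        frac = fw.contact_arc_mm / ds - k
        cp = (1 - frac) * fw.shape_mm[k] + frac * fw.shape_mm[k + 1]
        inv, diag = wg.base_reactions_from_shape(geometry, fw.shape_mm, cp)
        rel = np.abs(inv.as_array() - fw.reactions.as_array()) / np.abs(fw.reactions.as_array())
        assert np.all(rel < 0.01)
        assert not diag["low_confidence"]

    def test_no_contact_gives_exact_zeros(self, geometry):
        shape = geometry.undeflected_nodes_mm()
        out, _ = wg.base_reactions_from_shape(geometry, shape, None, contact=False)
        assert out.as_array().tolist() == [0.0, 0.0, 0.0]

    def test_doubled_load_scales_transverse_reactions(self, geometry):
        f1 = wg.deflect_whisker(geometry, wg.ContactConstraint((15.0, 0.1)))
        f2 = wg.deflect_whisker(geometry, wg.ContactConstraint((15.0, 0.2)))
        ds = geometry.ds_mm

        def cp(fw):
            k = int(fw.contact_arc_mm / ds)
            frac = fw.contact_arc_mm / ds - k
            return (1 - frac) * fw.shape_mm[k] + frac * fw.shape_mm[k + 1]

        r1, _ = wg.base_reactions_from_shape(geometry, f1.shape_mm, cp(f1))
        r2, _ = wg.base_reactions_from_shape(geometry, f2.shape_mm, cp(f2))
        assert r2.fy_uN == pytest.approx(2 * r1.fy_uN, rel=0.05)
        assert r2.m_uNm == pytest.approx(2 * r1.m_uNm, rel=0.05)

    def test_contact_without_point_errors(self, geometry):
        shape = geometry.undeflected_nodes_mm()
        with pytest.raises(ValueError):
            wg.base_reactions_from_shape(geometry, shape, None, contact=True)

    def test_too_few_nodes_errors(self, geometry):
        with pytest.raises(ValueError):
            wg.base_reactions_from_shape(geometry, np.zeros((5, 2)), (1.0, 1.0))


class TestGeometryValidation:
    def test_bad_radii(self):
        with pytest.raises(ValueError):
            wg.WhiskerGeometry(base_radius_um=2.0, tip_radius_um=3.0)

    def test_bad_constraint(self):
        with pytest.raises(ValueError):
            wg.ContactConstraint((0.0, 0.0))
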