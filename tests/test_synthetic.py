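"""Synthetic cohort generator: shapes, warps, A-scans, determinism."""

import numpy as np
import pytest
from scipy.integrate import quad

import foveametry as fm
from foveametry import Group, Layer
from foveametry.errors import ConfigurationError, InvalidWarpError


class TestControlProfiles:
    def test_sigmoid_limits(self):
        """Zero central residual gives zero FC thickness, rising to the rim value."""
        params = fm.ShapeParams(rim_um=40.0, centre_um=500.0, width_um=150.0,
                                central_um=0.0)
        fn = fm.control_shape(Layer.INL, params)
        assert fn(0.0) == pytest.approx(0.0, abs=1e-12)
        assert fn(1e6) == pytest.approx(40.0, rel=1e-9)

    def test_default_fc_anchors(self):
        """Default control shapes reproduce the FC calibration anchors:
        summed layers 185 µm total, residual IRL (GCL+IPL + INL) 8 µm."""
        t0 = {ly: float(fm.control_shape(ly, fm.synthetic.DEFAULT_CONTROL_SHAPES[ly])(0.0))
              for ly in Layer}
        assert t0[Layer.GCL_IPL] + t0[Layer.INL] == pytest.approx(8.0, abs=1e-9)
        assert sum(t0.values()) == pytest.approx(185.0, abs=1e-9)

    def test_irl_central_residual_exact(self):
        params = fm.ShapeParams(rim_um=40.0, centre_um=500.0, width_um=150.0,
                                central_um=8.0)
        assert fm.control_shape(Layer.INL, params)(0.0) == pytest.approx(8.0, abs=1e-12)

    def test_same_seed_bit_identical(self):
        a = fm.make_control_profile(Layer.INL, noise_sd_um=2.0, seed=42)
        b = fm.make_control_profile(Layer.INL, noise_sd_um=2.0, seed=42)
        assert np.array_equal(a.thickness_um, b.thickness_um)

    def test_invalid_shape_params(self):
        with pytest.raises(ConfigurationError):
            fm.ShapeParams(rim_um=40.0, centre_um=500.0, width_um=0.0)
        with pytest.raises(ConfigurationError):
            fm.make_control_profile(Layer.INL, grid_um=np.array([]))


class TestWarp:
    def test_identity_warp(self, control_inl):
        warped = fm.apply_retardation_warp(control_inl, fm.WarpSpec(0.0, 300.0))
        assert np.allclose(warped.profile.thickness_um, control_inl.thickness_um,
                           rtol=1e-9)
        assert warped.true_retardation(500.0) == pytest.approx(0.0, abs=1e-12)

    def test_linear_capped_closed_form(self):
        """Constant thickness t under psi = (1+a)e scales to t(1+a) with
        retardation E*a/(1+a) (hand integration of the mass balance)."""
        e = np.linspace(0.0, 1000.0, 41)
        prof = fm.LayerProfile(layer=Layer.OPL, eccentricity_um=e,
                               thickness_um=np.full_like(e, 20.0))
        alpha = 0.25
        warp = fm.WarpSpec(r_max_um=alpha * 4000.0, lambda_um=4000.0,
                           form=fm.WarpForm.LINEAR_CAPPED)
        warped = fm.apply_retardation_warp(prof, warp)
        assert np.allclose(warped.profile.thickness_um, 20.0 * (1 + alpha), rtol=1e-6)
        for E in (300.0, 700.0):
            assert warp.true_retardation(E) == pytest.approx(
                E * alpha / (1 + alpha), rel=1e-12)

    @pytest.mark.parametrize("form", list(fm.WarpForm))
    @pytest.mark.parametrize("r_max,lam", [(60.0, 400.0), (150.0, 300.0), (420.0, 300.0)])
    def test_mass_conservation(self, form, r_max, lam):
        """The warped thickness integrates over the compressed domain to the
        control mass over the original domain (change of variables)."""
        warp = fm.WarpSpec(r_max, lam, form=form)
        fn_c = fm.control_shape(Layer.GCL_IPL,
                                fm.synthetic.DEFAULT_CONTROL_SHAPES[Layer.GCL_IPL])
        ctrl = fm.make_control_profile(Layer.GCL_IPL)
        warped = fm.apply_retardation_warp(ctrl, warp, control_fn=fn_c)
        e_max = 1200.0
        m_pg, _ = quad(lambda e: float(warped.thickness_fn(e)), 0.0,
                       warp.psi_inv(e_max), limit=200)
        m_c, _ = quad(lambda e: float(fn_c(e)), 0.0, e_max, limit=200)
        assert m_pg == pytest.approx(m_c, rel=1e-6)

    def test_psi_inverse_roundtrip(self):
        warp = fm.WarpSpec(150.0, 300.0)
        for E in (1.0, 300.0, 900.0):
            assert warp.psi(warp.psi_inv(E)) == pytest.approx(E, rel=1e-9)

    def test_retardation_monotone_in_r_max(self):
        """Stronger blockage never decreases the true retardation at fixed E."""
        r = [fm.WarpSpec(rm, 300.0).true_retardation(500.0)
             for rm in (0.0, 50.0, 150.0, 420.0)]
        assert all(x >= 0 for x in r)
        assert r == sorted(r)

    def test_invalid_warp(self):
        with pytest.raises(InvalidWarpError):
            fm.WarpSpec(-1.0, 300.0)
        with pytest.raises(InvalidWarpError):
            fm.WarpSpec(100.0, 0.0)


class TestAscan:
    def test_zero_softness_boxcar_boundaries(self):
        prof = fm.synthesize_ascan([("OPL", 100.0, 112.0, 0.9)], step_um=1.0)
        assert prof.true_bands == (("OPL", 100.0, 112.0),)
        inside = (prof.depth_um >= 100.0) & (prof.depth_um <= 112.0)
        assert np.all(prof.reflectivity[inside] == 0.9)
        assert np.all(prof.reflectivity[~inside] == 0.0)

    def test_soft_edges_half_height_at_boundaries(self):
        """Error-function edges put the half-height level exactly at the
        stored boundaries of a well-separated band."""
        prof = fm.synthesize_ascan([("OPL", 100.0, 130.0, 0.8)], step_um=0.5,
                                   edge_softness_um=3.0)
        for b in (100.0, 130.0):
            idx = int(np.argmin(np.abs(prof.depth_um - b)))
            assert prof.reflectivity[idx] == pytest.approx(0.4, rel=1e-6)

    def test_same_seed_identical(self):
        kw = dict(step_um=1.0, noise_sd=0.05, seed=7)
        a = fm.synthesize_ascan([("OPL", 100.0, 110.0, 0.8)], **kw)
        b = fm.synthesize_ascan([("OPL", 100.0, 110.0, 0.8)], **kw)
        assert np.array_equal(a.reflectivity, b.reflectivity)

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ConfigurationError):
            fm.synthesize_ascan([("A", 100.0, 120.0, 0.8), ("B", 110.0, 130.0, 0.5)])


class TestCohort:
    def test_control_only_empty_truth(self):
        cfg = fm.CohortConfig(groups=(), seed=0)
        cohort = fm.generate_cohort(cfg)
        assert cohort.ground_truth.empty
        assert all(p.group is Group.C for p in cohort.profiles)

    def test_ground_truth_closed_form(self):
        """Truth at E=900 matches root-finding on the stated psi."""
        warp = fm.WarpSpec(150.0, 300.0)
        cfg = fm.CohortConfig(groups=(fm.GroupSpec(Group.PG2, warp),), seed=0)
        cohort = fm.generate_cohort(cfg)
        row = cohort.ground_truth.query("eccentricity_um == 900").iloc[0]
        from scipy.optimize import brentq

        inv = brentq(lambda x: x + 150.0 * (1 - np.exp(-x / 300.0)) - 900.0, 0, 900)
        assert row.true_retardation_um == pytest.approx(900.0 - inv, abs=1e-9)

    def test_seed_changes_noise_not_truth(self):
        warp = fm.WarpSpec(150.0, 300.0)

        def make(seed):
            return fm.generate_cohort(fm.CohortConfig(
                groups=(fm.GroupSpec(Group.PG2, warp, noise_sd_um=2.0),), seed=seed))

        a, b = make(0), make(1)
        assert a.ground_truth.equals(b.ground_truth)
        pa = [p for p in a.profiles if p.group is Group.PG2][0]
        pb = [p for p in b.profiles if p.group is Group.PG2][0]
        assert not np.array_equal(pa.thickness_um, pb.thickness_um)

    def test_duplicate_groups_rejected(self):
        warp = fm.WarpSpec(150.0, 300.0)
        with pytest.raises(ConfigurationError):
            fm.CohortConfig(groups=(fm.GroupSpec(Group.PG2, warp),
                                    fm.GroupSpec(Group.PG2, warp)), seed=0)

    def test_grid_must_cover_window(self):
        with pytest.raises(ConfigurationError):
            fm.CohortConfig(groups=(), grid_um=np.arange(0.0, 500.0, 25.0), seed=0)
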