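"""Spline fitting, cumulative curves and horizontal-displacement estimation."""

import numpy as np
import pytest

import foveametry as fm
from foveametry import Group, Layer
from foveametry.errors import (
    EccentricityRangeError,
    FitError,
    UnreachableValueError,
)
from conftest import warp_recovery_errors


def profile_from(e, t, layer=Layer.INL, group=Group.SYNTH):
    return fm.LayerProfile(layer=layer, eccentricity_um=np.asarray(e, float),
                           thickness_um=np.asarray(t, float), group=group)


class TestSplineFit:
    def test_reproduces_straight_line(self):
        e = np.linspace(0.0, 1000.0, 11)
        prof = profile_from(e, 5.0 + 0.03 * e)
        fit = fm.fit_thickness_spline(prof)
        x = np.linspace(0.0, 1000.0, 333)
        assert np.allclose(fit(x), 5.0 + 0.03 * x, atol=1e-9)

    def test_reproduces_constant(self, constant_profile):
        fit = fm.fit_thickness_spline(constant_profile)
        assert np.allclose(fit(np.linspace(0, 1000, 97)), 40.0, atol=1e-9)

    def test_smoothing_reduces_noise(self):
        """GCV smoothing on a noisy sigmoid: residual sd about the clean
        curve stays below 1.5x the injected noise sd (100-sample profile)."""
        rng = np.random.default_rng(11)
        e = np.linspace(0.0, 1200.0, 100)
        clean = 40.0 / (1.0 + np.exp(-(e - 500.0) / 150.0))
        noisy = np.maximum(clean + rng.normal(0, 2.0, e.shape), 0.0)
        fit = fm.fit_thickness_spline(profile_from(e, noisy), smoothing="gcv")
        resid_sd = np.std(fit(e) - clean)
        assert resid_sd <= 3.0

    def test_too_few_points_rejected_at_construction(self):
        from foveametry.errors import SchemaError

        with pytest.raises(SchemaError):
            profile_from([0, 100, 200], [1, 2, 3])


class TestCumulativeCurve:
    def test_constant_thickness_linear_cumulative(self, constant_profile):
        cum = fm.cumulative_curve(constant_profile)
        assert cum(0.0) == 0.0
        for E in (250.0, 500.0, 1000.0):
            assert cum(E) == pytest.approx(40.0 * E, rel=1e-6)

    def test_linear_thickness_quadratic_cumulative(self):
        e = np.linspace(0.0, 1000.0, 21)
        cum = fm.cumulative_curve(profile_from(e, 0.05 * e))
        for E in (200.0, 600.0, 1000.0):
            assert cum(E) == pytest.approx(0.05 * E**2 / 2.0, rel=1e-6)

    def test_nondecreasing_everywhere(self, control_inl):
        cum = fm.cumulative_curve(control_inl)
        vals = cum(np.linspace(0.0, cum.e_max_um, 601))
        assert np.all(np.diff(vals) >= -1e-9)

    def test_extension_to_zero_constant(self):
        """Profiles starting above 0 µm extend inward at the innermost value."""
        e = np.linspace(200.0, 1000.0, 17)
        cum = fm.cumulative_curve(profile_from(e, np.full_like(e, 10.0)))
        assert cum(200.0) == pytest.approx(10.0 * 200.0, rel=1e-9)

    def test_negative_spline_lobes_clipped(self):
        """Interpolating a spiky profile swings negative between samples;
        the cumulative must still be non-decreasing (clipped integrand)."""
        e = np.linspace(0.0, 1000.0, 21)
        t = np.zeros_like(e)
        t[10] = 50.0
        cum = fm.cumulative_curve(profile_from(e, t))
        vals = cum(np.linspace(0.0, 1000.0, 501))
        assert np.all(np.diff(vals) >= -1e-9)
        assert cum.total_um2 > 0

    def test_e_max_outside_domain(self, constant_profile):
        with pytest.raises(EccentricityRangeError):
            fm.cumulative_curve(constant_profile, 1500.0)


class TestRetardationAt:
    def test_identical_curves_zero_everywhere(self, control_inl):
        c1 = fm.cumulative_curve(control_inl)
        c2 = fm.cumulative_curve(control_inl)
        for E in (100.0, 300.0, 500.0, 900.0):
            assert fm.retardation_at(c1, c2, E).retardation_um == 0.0

    def test_doubled_thickness_half_eccentricity(self):
        """Control t, preterm 2t: the preterm holds control's mass at E
        already at E/2, so retardation is E/2 (hand integration)."""
        e = np.linspace(0.0, 1000.0, 21)
        cum_c = fm.cumulative_curve(profile_from(e, np.full_like(e, 10.0)))
        cum_pg = fm.cumulative_curve(profile_from(e, np.full_like(e, 20.0)))
        for E in (300.0, 500.0, 800.0):
            assert fm.retardation_at(cum_c, cum_pg, E).retardation_um == pytest.approx(
                E / 2.0, rel=1e-6)

    def test_known_warp_noise_free_recovery(self, control_inl):
        """Cum_PG = Cum_C(psi): recovered retardation matches E - psi_inv(E)
        within 2 µm on noise-free profiles."""
        warp = fm.WarpSpec(150.0, 300.0)
        warped = fm.apply_retardation_warp(
            control_inl, warp,
            control_fn=fm.control_shape(Layer.INL,
                                        fm.synthetic.DEFAULT_CONTROL_SHAPES[Layer.INL]))
        cum_c = fm.cumulative_curve(control_inl)
        cum_pg = fm.cumulative_curve(warped.profile)
        for E in (300.0, 500.0, 700.0, 900.0):
            est = fm.retardation_at(cum_c, cum_pg, E)
            assert est.retardation_um == pytest.approx(warp.true_retardation(E), abs=2.0)
            assert est.residual_um == pytest.approx(E - est.retardation_um, abs=1e-9)

    def test_unreachable_value_reported(self):
        """A preterm curve with less total mass than the control ordinate
        raises rather than silently clipping."""
        e = np.linspace(0.0, 1000.0, 21)
        cum_c = fm.cumulative_curve(profile_from(e, np.full_like(e, 10.0)))
        cum_pg = fm.cumulative_curve(profile_from(e, np.full_like(e, 1.0)))
        with pytest.raises(UnreachableValueError):
            fm.retardation_at(cum_c, cum_pg, 900.0)

    def test_layer_mismatch_rejected(self, control_inl):
        other = fm.make_control_profile(Layer.OPL)
        with pytest.raises(EccentricityRangeError):
            fm.retardation_at(fm.cumulative_curve(control_inl),
                              fm.cumulative_curve(other), 300.0)

    def test_plateau_resolves_to_smallest_eccentricity(self):
        """Zero-thickness stretch in the preterm profile: the crossing on
        the flat cumulative segment maps to the plateau's left edge."""
        e = np.linspace(0.0, 1000.0, 41)
        t_pg = np.where(e < 300.0, 10.0, np.where(e < 600.0, 0.0, 10.0))
        t_c = np.full_like(e, 3.0)
        cum_c = fm.cumulative_curve(profile_from(e, t_c))
        cum_pg = fm.cumulative_curve(profile_from(e, t_pg))
        # control mass at E=900: 2700 µm²; preterm reaches 2700 at e=270
        # and stays there through the plateau — smallest preimage wins
        est = fm.retardation_at(cum_c, cum_pg, 900.0)
        assert est.residual_um == pytest.approx(270.0, abs=2.0)

    def test_scale_invariance_exact(self, control_inl):
        """Doubling both profiles' thickness leaves retardation bit-identical."""
        from dataclasses import replace

        warped = fm.apply_retardation_warp(control_inl, fm.WarpSpec(150.0, 300.0))
        c2 = replace(control_inl, thickness_um=control_inl.thickness_um * 2.0)
        p2 = replace(warped.profile, thickness_um=warped.profile.thickness_um * 2.0)
        r1 = fm.retardation_at(fm.cumulative_curve(control_inl),
                               fm.cumulative_curve(warped.profile), 500.0)
        r2 = fm.retardation_at(fm.cumulative_curve(c2),
                               fm.cumulative_curve(p2), 500.0)
        assert r1.retardation_um == r2.retardation_um

    def test_brute_force_oracle_agreement(self, control_inl):
        """Bisection inverse agrees within 1 µm with a 0.5 µm grid scan."""
        warp = fm.WarpSpec(150.0, 300.0)
        warped = fm.apply_retardation_warp(control_inl, warp)
        cum_c = fm.cumulative_curve(control_inl)
        cum_pg = fm.cumulative_curve(warped.profile)
        grid = np.arange(0.0, cum_pg.e_max_um + 0.25, 0.5)
        pg_vals = cum_pg(grid)
        for E in (300.0, 500.0, 700.0, 900.0):
            est = fm.retardation_at(cum_c, cum_pg, E)
            brute = grid[int(np.argmax(pg_vals >= cum_c(E)))]
            assert abs((E - brute) - est.retardation_um) <= 1.0


class TestRetardationProfileAndSummary:
    def test_default_grid_yields_four_estimates(self, control_inl):
        warped = fm.apply_retardation_warp(control_inl, fm.WarpSpec(60.0, 400.0))
        ests = fm.retardation_profile(fm.cumulative_curve(control_inl),
                                      fm.cumulative_curve(warped.profile),
                                      (300.0, 500.0, 700.0, 900.0))
        assert len(ests) == 4 and all(e.ok for e in ests)

    def test_empty_eccentricity_list(self, control_inl):
        c = fm.cumulative_curve(control_inl)
        assert fm.retardation_profile(c, c, ()) == []

    def test_failures_recorded_not_fatal(self):
        e = np.linspace(0.0, 1000.0, 21)
        cum_c = fm.cumulative_curve(profile_from(e, np.full_like(e, 10.0)))
        cum_pg = fm.cumulative_curve(profile_from(e, np.full_like(e, 1.0)))
        ests = fm.retardation_profile(cum_c, cum_pg, (50.0, 900.0))
        assert ests[0].ok
        assert not ests[1].ok and "exceeds" in ests[1].error

    def test_single_estimate_summary(self):
        est = fm.RetardationEstimate(layer=Layer.INL, group=Group.PG2,
                                     eccentricity_um=500.0, retardation_um=77.0,
                                     residual_um=423.0)
        s = fm.group_summary([est])
        assert s.mean_um == s.min_um == s.max_um == 77.0
        assert s.n_cells == 1

    def test_empty_window_rejected(self):
        est = fm.RetardationEstimate(layer=Layer.INL, group=Group.PG2,
                                     eccentricity_um=100.0, retardation_um=10.0,
                                     residual_um=90.0)
        with pytest.raises(EccentricityRangeError):
            fm.group_summary([est], window_um=(300.0, 900.0))


class TestRecoveryProperties:
    def test_shift_consistency_under_noise(self):
        """Control vs itself warped (r_max 150, lambda 300) with shared
        segmentation noise sd 2 µm on the 25 µm grid: recovery within
        5 µm at the analysis eccentricities (two seeds; the acceptance
        suite sweeps ten)."""
        warp = fm.WarpSpec(150.0, 300.0)
        for seed in (0, 1):
            assert warp_recovery_errors(warp, seed) <= 5.0

    def test_severe_warp_noise_floor(self):
        """Severe compression (psi' ~ 2.4 centrally) aliases grid-scale
        noise and degrades recovery; it must stay inside the analysed
        ~25 µm noise floor rather than silently blowing up."""
        warp = fm.WarpSpec(420.0, 300.0)
        worst = max(warp_recovery_errors(warp, seed) for seed in (0, 1, 2))
        assert worst <= 25.0

    def test_estimate_monotone_in_r_max(self, control_inl):
        """Stronger synthetic blockage never decreases estimated retardation."""
        cum_c = fm.cumulative_curve(control_inl)
        prev = -1.0
        for r_max in (0.0, 60.0, 150.0, 300.0):
            warped = fm.apply_retardation_warp(control_inl, fm.WarpSpec(r_max, 300.0))
            est = fm.retardation_at(cum_c, fm.cumulative_curve(warped.profile), 500.0)
            assert est.retardation_um >= prev - 1e-9
            prev = est.retardation_um
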