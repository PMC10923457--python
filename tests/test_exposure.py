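"""Exposure analysis: H_smoke, zones, profiles, ppm conversion, report."""

import numpy as np
import pytest

import theatresmoke as ts
from theatresmoke.exposure import (ZONE_LABELS, build_report, classify_zones,
                                   co_ppm, compute_H_smoke, extract_profile,
                                   fit_H_smoke_curve, published_h_smoke)
from theatresmoke.solver import FieldState


def make_state(mesh, **overrides):
    z = np.zeros(mesh.n)
    fields = dict(u=z.copy(), v=z.copy(), w=z.copy(), p=z.copy(),
                  T=np.full(mesh.n, 300.15), k=z + 1e-8, eps=z + 1e-10,
                  converged=True)
    fields.update(overrides)
    return FieldState(mesh=mesh, **fields)


class TestHsmoke:
    def test_sine_profile_zero_at_1p9(self, small_mesh):
        """w(z) = sin(pi (z-0.9)) above the incision crosses zero at 1.9 m."""
        zc = small_mesh.centers(2)
        w = np.zeros(small_mesh.n)
        prof = np.sin(np.pi * (zc - 0.9))
        prof[zc < 0.9] = 0.1
        w[:, :, :] = prof[None, None, :]
        st = make_state(small_mesh, w=w)
        res = compute_H_smoke(st)
        assert res.status == "ok"
        assert res.height == pytest.approx(1.9, abs=small_mesh.d[2] / 2)

    def test_pure_downflow_undefined(self, small_mesh):
        st = make_state(small_mesh, w=np.full(small_mesh.n, -0.1))
        res = compute_H_smoke(st)
        assert res.status == "undefined"
        assert np.isnan(res.height)

    def test_plume_reaching_ceiling_flagged(self, small_mesh):
        st = make_state(small_mesh, w=np.full(small_mesh.n, +0.1))
        res = compute_H_smoke(st)
        assert res.status == "ceiling"
        assert res.height == pytest.approx(3.0)


class TestPublishedCurve:
    def test_endpoint_200C(self):
        assert published_h_smoke(200.0) == pytest.approx(1.1106, rel=1e-6)

    def test_endpoint_500C(self):
        assert published_h_smoke(500.0) == pytest.approx(1.4340, rel=1e-6)

    def test_matches_printed_values_within_1p5_percent(self):
        assert published_h_smoke(200.0) == pytest.approx(1.1, rel=0.015)
        assert published_h_smoke(500.0) == pytest.approx(1.45, rel=0.015)


class TestHsmokeFit:
    def test_exact_quadratic_recovery(self):
        coeffs = (0.9, 1e-3, 1e-6)
        pts = [(t, coeffs[0] + coeffs[1] * t + coeffs[2] * t ** 2)
               for t in (200, 350, 500)]
        fit = fit_H_smoke_curve(pts)
        np.testing.assert_allclose(fit.coeffs, coeffs, rtol=1e-9)
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_H_smoke_curve([(200, 1.1), (500, 1.45)])


class TestCoPpm:
    def test_zero_fraction(self):
        assert co_ppm(0.0) == 0.0

    def test_pure_gas_limit(self):
        assert co_ppm(1.0, mixture_molar_mass=28.01) == pytest.approx(1e6)

    def test_dilute_arithmetic(self):
        assert float(co_ppm(9.66e-6)) == pytest.approx(9.99, abs=0.01)

    def test_linearity(self):
        y = np.array([1e-6, 2e-6, 4e-6])
        out = co_ppm(y)
        assert out[1] / out[0] == pytest.approx(2.0)
        assert out[2] / out[0] == pytest.approx(4.0)

    def test_bad_molar_mass(self):
        with pytest.raises(ValueError):
            co_ppm(1e-6, mixture_molar_mass=0.0)


class TestZones:
    def test_zero_velocity_all_other(self, small_mesh):
        st = make_state(small_mesh)
        zones = classify_zones(st, small_mesh)
        assert set(np.unique(zones[small_mesh.fluid])) == {0}

    def test_upwelling_column_labelled(self, small_mesh):
        w = np.zeros(small_mesh.n)
        i, j, k0 = small_mesh.incision_cell
        w[i, j, k0:k0 + 3] = 0.2
        st = make_state(small_mesh, w=w)
        zones = classify_zones(st, small_mesh)
        assert (zones[i, j, k0:k0 + 3] == 1).all()

    def test_wall_updraft_labelled(self, small_mesh):
        w = np.zeros(small_mesh.n)
        w[0, :, :] = 0.05    # updraft hugging the x=0 wall
        st = make_state(small_mesh, w=w)
        zones = classify_zones(st, small_mesh)
        assert (zones[0, :, 2:-2] == 7).all()

    def test_partition_exclusive_and_exhaustive(self, hot_case_small):
        zones = classify_zones(hot_case_small)
        mesh = hot_case_small.mesh
        assert (zones[mesh.fluid] >= 0).all()
        assert (zones[~mesh.fluid] == -1).all()
        vols = [(zones == lab).sum() for lab in ZONE_LABELS]
        assert sum(vols) == mesh.fluid.sum()


class TestProfiles:
    def test_constant_field_constant_profile(self, small_mesh):
        f = np.full(small_mesh.n, 3.3)
        s, v = extract_profile(f, small_mesh, (1, 3, 1), (7, 3, 1), 40)
        assert np.allclose(v, 3.3)
        assert s[-1] == pytest.approx(6.0)

    def test_linear_field_exact_interpolation(self, small_mesh):
        xc = small_mesh.centers(0)
        f = np.broadcast_to(2.0 * xc[:, None, None] + 1.0, small_mesh.n).copy()
        s, v = extract_profile(f, small_mesh, (1.0, 3.0, 1.5), (7.0, 3.0, 1.5), 25)
        assert np.allclose(v, 2.0 * (1.0 + s) + 1.0, rtol=1e-12)

    def test_endpoint_outside_room_rejected(self, small_mesh):
        with pytest.raises(ValueError, match="outside"):
            extract_profile(np.zeros(small_mesh.n), small_mesh,
                            (0, 0, 0), (9.0, 3.0, 1.0))


class TestReport:
    def test_zero_source_report_wellformed(self, unforced_isothermal_state):
        rep = build_report(unforced_isothermal_state, tip_temp=500.0)
        assert not any(rep.threshold_flags.values())
        assert abs(sum(rep.zone_volume_fractions.values()) - 1.0) < 1e-9
        text = rep.to_json()
        assert '"threshold_flags"' in text

    def test_hot_case_concentrations_positive_near_wound(self, hot_case_small):
        rep = build_report(hot_case_small, tip_temp=500.0)
        assert rep.wound_zone["c_tar_g_m3"] > 0
        assert rep.wound_zone["c_particle_g_m3"] > rep.wound_zone["c_tar_g_m3"]

    def test_patient_profile_peaks_near_incision(self, hot_case_small):
        """Nose-height waste-gas concentration peaks within 0.5 m of the
        cutting position along the table centre line."""
        rep = build_report(hot_case_small, tip_temp=500.0)
        prof = rep.patient_profiles["waste_gas_mass_fraction"]
        s = np.array(prof["position_m"])
        v = np.array(prof["value"])
        x_incision = 4.0 - 3.1   # arc length of the incision on the line
        assert abs(s[np.argmax(v)] - x_incision) <= 0.5
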