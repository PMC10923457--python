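"""Calibration polynomials: evaluation, inversion, refitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from theatresmoke.empirical import (CalibrationSet, PowerSweepRecord,
                                    SourceSpec, eval_particle_rate,
                                    eval_tar_rate, eval_tip_temperature,
                                    eval_waste_gas_flow, fit_calibration,
                                    make_source_spec, mole_to_mass_fractions,
                                    power_for_temperature)


def horner(coeffs, x):
    acc = 0.0
    for c in reversed(coeffs):
        acc = acc * x + c
    return acc


@pytest.mark.parametrize("func,power,expected", [
    (eval_tip_temperature, 0.0, 270.0),
    (eval_tip_temperature, 80.0, 510.8),
    (eval_waste_gas_flow, 0.0, 9.30e-6),
    (eval_waste_gas_flow, 80.0, 5.1532e-5),
    (eval_waste_gas_flow, 20.0, 1.1266e-5),
    (eval_tar_rate, 0.0, 2.82e-3),
    (eval_tar_rate, 80.0, 0.07970),
    (eval_tar_rate, 20.0, 9.908e-3),
])
def test_polynomial_evaluation(func, power, expected):
    assert func(power) == pytest.approx(expected, rel=1e-9)


def test_particle_rate_clamp():
    # the fitted cubic is negative at zero power; the physical rate is not
    assert eval_particle_rate(0.0, clamp=False) == pytest.approx(-4.14e-3)
    assert eval_particle_rate(0.0, clamp=True) == 0.0
    assert eval_particle_rate(80.0) == pytest.approx(0.17668, rel=1e-4)


@pytest.mark.parametrize("power,temp", [(20, 200), (60, 300), (70, 400), (80, 500)])
def test_printed_power_temperature_correspondence(power, temp):
    """The four canonical operating points round to 100-degC levels."""
    assert round(eval_tip_temperature(power) / 100.0) * 100 == temp


@pytest.mark.parametrize("func", [eval_tip_temperature, eval_waste_gas_flow,
                                  eval_tar_rate, eval_particle_rate])
def test_negative_power_rejected(func):
    with pytest.raises(ValueError):
        func(-1.0)


@given(st.floats(min_value=0.0, max_value=100.0))
@settings(max_examples=200, deadline=None)
def test_evaluation_matches_horner_oracle(power):
    calib = CalibrationSet()
    for func, coeffs in [(eval_tip_temperature, calib.temp_coeffs),
                         (eval_waste_gas_flow, calib.flow_coeffs),
                         (eval_tar_rate, calib.tar_coeffs)]:
        assert func(power, calib) == pytest.approx(horner(coeffs, power),
                                                   rel=1e-13, abs=1e-300)
    assert eval_particle_rate(power, calib, clamp=False) == pytest.approx(
        horner(calib.particle_coeffs, power), rel=1e-13, abs=1e-300)


def test_monotonicity_on_operating_range():
    p = np.linspace(24.3, 100, 500)
    t = [eval_tip_temperature(v) for v in p]
    assert np.all(np.diff(t) > 0)
    p = np.linspace(20, 100, 500)
    g = [eval_waste_gas_flow(v) for v in p]
    assert np.all(np.diff(g) > 0)
    assert all(v > 0 for v in g)


class TestInverse:
    def test_continuous_inverse(self):
        power, unreachable = power_for_temperature(500.0)
        assert power == pytest.approx(78.97, abs=0.01)
        assert not unreachable

    def test_lookup_mode_uses_printed_powers(self):
        assert power_for_temperature(500.0, lookup=True) == (80.0, False)
        assert power_for_temperature(300.0, lookup=True) == (60.0, False)

    def test_unreachable_temperature_returns_vertex(self):
        power, unreachable = power_for_temperature(200.0)
        assert unreachable
        assert power == pytest.approx(4.59 / (2 * 0.095), rel=1e-9)

    @given(st.floats(min_value=24.3, max_value=100.0))
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_identity_above_vertex(self, power):
        t = eval_tip_temperature(power)
        p2, flag = power_for_temperature(t)
        assert not flag
        assert p2 == pytest.approx(power, rel=1e-9)


class TestFit:
    def _records(self, calib, powers, rng=None, cv=0.0):
        recs = []
        for p in powers:
            f = (1.0 + rng.normal(0, cv, 4)) if rng is not None else np.ones(4)
            recs.append(PowerSweepRecord(
                power=p,
                tip_temp=eval_tip_temperature(p, calib) * f[0],
                waste_gas_flow=eval_waste_gas_flow(p, calib) * f[1],
                tar_rate=eval_tar_rate(p, calib) * f[2],
                particle_rate=max(eval_particle_rate(p, calib, clamp=False), 0) * f[3]))
        return recs

    def test_noiseless_roundtrip_recovers_defaults(self, default_calib):
        recs = self._records(default_calib, [20, 30, 40, 50, 60, 70, 80])
        fitted, rss = fit_calibration(recs)
        for name in ("temp_coeffs", "flow_coeffs", "tar_coeffs"):
            np.testing.assert_allclose(getattr(fitted, name),
                                       getattr(default_calib, name), rtol=1e-8)
        assert all(v < 1e-12 for v in rss.values())

    def test_noisy_fit_matches_normal_equations_oracle(self, default_calib):
        rng = np.random.default_rng(42)
        recs = self._records(default_calib, [20, 30, 40, 50, 60, 70, 80],
                             rng=rng, cv=0.02)
        fitted, _ = fit_calibration(recs)
        # independent oracle: explicit normal-equations solve
        p = np.array([r.power for r in recs])
        X = np.vander(p, 3, increasing=True)
        y = np.array([r.tip_temp for r in recs])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fitted.temp_coeffs, beta, rtol=1e-8)

    def test_underdetermined_cubic_raises(self, default_calib):
        recs = self._records(default_calib, [20, 40, 60])
        with pytest.raises(ValueError, match="distinct powers"):
            fit_calibration(recs)


class TestSourceSpec:
    def test_canonical_500C_source(self):
        spec = make_source_spec(500.0)
        assert spec.power == 80.0
        assert spec.volume_flow == pytest.approx(5.1532e-5, rel=1e-9)
        assert spec.tar_rate == pytest.approx(0.07970, rel=1e-4)
        assert spec.particle_rate == pytest.approx(0.17668, rel=1e-4)
        assert spec.temperature == 500.0

    def test_canonical_300C_uses_60W(self):
        assert make_source_spec(300.0).power == 60.0

    def test_ambient_temperature_rejected(self):
        with pytest.raises(ValueError, match="ambient"):
            make_source_spec(27.0)

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError):
            make_source_spec(500.0, composition={"CO": 0.9, "CO2": 0.9})

    def test_mass_fractions_sum_below_one(self):
        mf = mole_to_mass_fractions({"CO": 0.25, "CO2": 0.45, "CH4": 0.06,
                                     "NH3": 0.04})
        assert 0 < sum(mf.values()) <= 1.0


def test_calibration_set_length_validation():
    with pytest.raises(ValueError):
        CalibrationSet(temp_coeffs=(1.0, 2.0))


def test_record_invariants():
    with pytest.raises(ValueError):
        PowerSweepRecord(power=-5, tip_temp=300, waste_gas_flow=1e-5,
                         tar_rate=0.01, particle_rate=0.01)
    with pytest.raises(ValueError):
        PowerSweepRecord(power=20, tip_temp=300, waste_gas_flow=-1e-5,
                         tar_rate=0.01, particle_rate=0.01)
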