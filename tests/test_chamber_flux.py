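"""Flux-estimation checks: deadband, unit conversion, linear/exponential
fits against brute-force oracles, fit selection, isotope arithmetic."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pyruflux.chamber_flux import (
    R_VPDB,
    ClosureSeries,
    FitResult,
    apply_deadband,
    delta13C_from_fluxes,
    excess_13C_flux,
    fit_exponential,
    fit_linear,
    isotopologue_fluxes,
    mole_fraction_slope_to_flux,
    process_closures,
    select_flux,
)
from pyruflux.synthetic import closure_from_flux, generate_scenario

from conftest import small_config

GEOM = dict(
    chamber_volume_m3=0.004076,
    collar_area_m2=0.0318,
    air_temperature_k=296.15,
    air_pressure_pa=101325.0,
)


def make_series(t, x12, x13, **overrides):
    meta = dict(
        chamber_id="S1C1R1", site="S1", label_position="C1",
        condition="pre_drought", closure_time_h=1.0, **GEOM,
    )
    meta.update(overrides)
    return ClosureSeries(t_rel=np.asarray(t, float), x12c=np.asarray(x12, float),
                         x13c=np.asarray(x13, float), **meta)


class TestDeadband:
    def test_removes_initial_samples_and_rezeroes(self):
        t = np.arange(390.0)
        s = make_series(t, 400 + 0.01 * t, 4 + 0.0001 * t)
        trimmed = apply_deadband(s, 30.0)
        assert len(trimmed.t_rel) == 360
        assert trimmed.t_rel[0] == 0.0

    def test_zero_deadband_is_identity(self):
        t = np.arange(100.0)
        s = make_series(t, np.full(100, 400.0), np.full(100, 4.0))
        trimmed = apply_deadband(s, 0.0)
        np.testing.assert_array_equal(trimmed.t_rel, t)

    def test_all_samples_inside_deadband_raises(self):
        s = make_series([0, 5, 10], [400, 400, 400], [4, 4, 4])
        with pytest.raises(ValueError):
            apply_deadband(s, 30.0)


class TestSlopeToFlux:
    def test_hand_arithmetic_example(self):
        f = mole_fraction_slope_to_flux(0.01, 0.004, 0.0318, 296.15, 101325.0)
        expected = 0.01 * 101325.0 * 0.004 / (8.314 * 296.15 * 0.0318)
        assert f == pytest.approx(expected, rel=1e-12)
        assert f == pytest.approx(0.0518, abs=5e-4)

    def test_zero_slope(self):
        assert mole_fraction_slope_to_flux(0.0, 0.004, 0.0318, 296.15, 101325.0) == 0.0

    def test_doubling_area_halves_flux(self):
        f1 = mole_fraction_slope_to_flux(0.01, 0.004, 0.0318, 296.15, 101325.0)
        f2 = mole_fraction_slope_to_flux(0.01, 0.004, 0.0636, 296.15, 101325.0)
        assert f2 == pytest.approx(f1 / 2, rel=1e-12)


class TestLinearFit:
    def test_exact_line_recovered(self):
        t = np.arange(0.0, 121.0, 2.0)
        s = make_series(t, 400 + 0.02 * t, np.full_like(t, 4.0))
        assert fit_linear(s).slope == pytest.approx(0.02, abs=1e-12)

    def test_constant_series_slope_zero(self):
        t = np.arange(0.0, 121.0, 2.0)
        s = make_series(t, np.full_like(t, 400.0), np.full_like(t, 4.0))
        assert fit_linear(s).slope == pytest.approx(0.0, abs=1e-14)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 121.0, 2.0)
        y = 400 + 0.015 * t + rng.normal(0, 0.05, t.shape)
        s = make_series(t, y, np.full_like(t, 4.0))
        # brute-force normal equations
        A = np.column_stack([t, np.ones_like(t)])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit_linear(s).slope == pytest.approx(beta[0], abs=1e-10)

    def test_too_few_samples_raises(self):
        s = make_series([0, 200], [400, 410], [4, 4])
        with pytest.raises(ValueError):
            fit_linear(s, window_s=120.0)


class TestExponentialFit:
    def test_noise_free_parameter_recovery(self):
        cs, c0, a = 600.0, 400.0, 0.002
        t = np.arange(0.0, 391.0, 2.0)
        y = cs + (c0 - cs) * np.exp(-a * t)
        s = make_series(t, y, np.zeros_like(t))
        fit = fit_exponential(s)
        assert fit.converged
        assert fit.params["cs"] == pytest.approx(cs, rel=1e-6)
        assert fit.params["c0"] == pytest.approx(c0, rel=1e-6)
        assert fit.params["a"] == pytest.approx(a, rel=1e-6)
        assert fit.slope == pytest.approx(a * (cs - c0), rel=1e-6)  # 0.4

    def test_near_linear_limit_matches_linear_fit(self):
        a = 1e-6
        t = np.arange(0.0, 391.0, 2.0)
        y = 400.0 + 0.02 * (-np.expm1(-a * t) / a)
        s = make_series(t, y, np.full_like(t, 4.0))
        exp_fit = fit_exponential(s)
        lin_fit = fit_linear(s)
        assert exp_fit.slope == pytest.approx(lin_fit.slope, rel=0.01)

    def test_constant_series_gives_zero_slope_or_failure(self):
        t = np.arange(0.0, 391.0, 2.0)
        s = make_series(t, np.full_like(t, 400.0), np.full_like(t, 4.0))
        fit = fit_exponential(s)
        assert (not fit.converged) or abs(fit.slope) < 1e-10

    def test_initial_slope_unbiased_under_noise(self):
        # < 2% bias of the mean recovered initial slope over 500 noisy closures
        cs, c0, a = 800.0, 420.0, 0.0015
        t = np.arange(0.0, 391.0, 2.0)
        clean = cs + (c0 - cs) * np.exp(-a * t)
        true_slope = a * (cs - c0)
        rng = np.random.default_rng(123)
        slopes = []
        for _ in range(500):
            y = clean + rng.normal(0, 0.05, t.shape)
            fit = fit_exponential(make_series(t, y, np.full_like(t, 4.0)))
            if fit.converged:
                slopes.append(fit.slope)
        assert len(slopes) > 480
        assert np.mean(slopes) == pytest.approx(true_slope, rel=0.02)


class TestSelectFlux:
    LIN = FitResult(slope=0.02, r2=0.990, residual_sd=0.1, converged=True, method="linear")

    def exp(self, r2=0.995, a=0.002, converged=True):
        return FitResult(slope=0.021, r2=r2, residual_sd=0.1, converged=converged,
                         method="exponential", params={"a": a})

    def test_exponential_preferred_when_adequate(self):
        chosen, flag = select_flux(self.LIN, self.exp())
        assert chosen.method == "exponential" and flag == "ok"

    def test_within_margin_still_exponential(self):
        chosen, _ = select_flux(self.LIN, self.exp(r2=0.945))
        assert chosen.method == "exponential"

    def test_nonconverged_falls_back_to_linear(self):
        chosen, flag = select_flux(self.LIN, self.exp(converged=False))
        assert chosen.method == "linear" and flag == "replaced_by_linear"

    def test_nonpositive_rate_falls_back(self):
        chosen, _ = select_flux(self.LIN, self.exp(a=-1e-4))
        assert chosen.method == "linear"

    def test_poor_exponential_r2_falls_back(self):
        chosen, _ = select_flux(self.LIN, self.exp(r2=0.90))
        assert chosen.method == "linear"

    def test_both_failed_rejected(self):
        bad = FitResult(slope=np.nan, r2=np.nan, residual_sd=np.nan, converged=False, method="linear")
        chosen, flag = select_flux(bad, self.exp(converged=False))
        assert chosen is None and flag == "rejected"


class TestIsotopologueFluxes:
    def test_constant_13c_channel_gives_zero_flux(self):
        t = np.arange(0.0, 121.0, 2.0)
        s = make_series(t, 400 + 0.02 * t, np.full_like(t, 4.6))
        f12, f13 = isotopologue_fluxes(s)
        assert f13 == pytest.approx(0.0, abs=1e-12)
        assert f12 > 0

    def test_total_equals_sum_of_isotopologues(self):
        rng = np.random.default_rng(9)
        t = np.arange(0.0, 121.0, 2.0)
        s = make_series(
            t,
            400 + 0.02 * t + rng.normal(0, 0.05, t.shape),
            4.5 + 3e-4 * t + rng.normal(0, 0.005, t.shape),
        )
        f12, f13 = isotopologue_fluxes(s)
        conv = mole_fraction_slope_to_flux(
            fit_linear(s).slope, GEOM["chamber_volume_m3"], GEOM["collar_area_m2"],
            GEOM["air_temperature_k"], GEOM["air_pressure_pa"],
        )
        assert f12 + f13 == pytest.approx(conv, rel=1e-9)


class TestDeltaArithmetic:
    def test_vpdb_ratio_gives_zero_permil(self):
        assert delta13C_from_fluxes(1.0, R_VPDB) == pytest.approx(0.0, abs=1e-12)

    def test_zero_13c_gives_minus_1000(self):
        assert delta13C_from_fluxes(1.0, 0.0) == -1000.0

    def test_direct_evaluation(self):
        expected = (0.0123 / R_VPDB - 1.0) * 1000.0  # ~ +100.2 permil
        assert delta13C_from_fluxes(1.0, 0.0123) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(100.2, abs=0.05)

    def test_nonpositive_12c_undefined(self):
        assert np.isnan(delta13C_from_fluxes(0.0, 0.01))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        ratio=st.floats(0.001, 0.1),
        scale=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, ratio, scale):
        d1 = delta13C_from_fluxes(1.0, ratio)
        d2 = delta13C_from_fluxes(scale, scale * ratio)
        assert d2 == pytest.approx(d1, rel=1e-9, abs=1e-9)


class TestExcess13C:
    def test_chamber_at_baseline_gives_zero(self):
        base = -25.0
        f13 = 1.0 * R_VPDB * (1 + base / 1000.0)
        excess, floored = excess_13C_flux(f13, 1.0, base)
        assert excess == pytest.approx(0.0, abs=1e-15) and not floored

    def test_arithmetic_example(self):
        excess, _ = excess_13C_flux(R_VPDB, 1.0, -25.0)
        assert excess == pytest.approx(R_VPDB * 0.025, rel=1e-9)
        assert excess == pytest.approx(2.795e-4, abs=1e-7)

    def test_additive_in_f13(self):
        e1, _ = excess_13C_flux(0.02, 1.0, -25.0)
        e2, _ = excess_13C_flux(0.04, 1.0, -25.0)
        assert e2 - e1 == pytest.approx(0.02, rel=1e-12)

    def test_negative_excess_floored_and_flagged(self):
        excess, floored = excess_13C_flux(0.0, 1.0, -25.0)
        assert excess == 0.0 and floored


class TestPipelineRoundTrip:
    def test_zero_noise_linear_closures_recover_generator_fluxes(self, clean_config):
        bundle = generate_scenario(clean_config, seed=1)
        fluxes = process_closures(bundle["closures"])
        assert (fluxes["qc_flag"] != "rejected").all()
        # pre-injection closures carry only the baseline flux; the linear
        # isotopologue channel reproduces it to numerical precision
        pre = fluxes[fluxes["closure_time_h"] < 0]
        lin_total = (pre["F_12C"] + pre["F_13C"]).to_numpy()
        assert lin_total == pytest.approx(
            np.full(len(pre), clean_config.baseline_co2_flux), rel=1e-9
        )
        assert pre["F_total"].to_numpy() == pytest.approx(
            np.full(len(pre), clean_config.baseline_co2_flux), rel=1e-4
        )
        assert pre["delta13C_permil"].to_numpy() == pytest.approx(
            np.full(len(pre), clean_config.baseline_delta13c), rel=1e-6
        )
        # excess flux at the closure start times matches the analytic pulse
        from pyruflux.synthetic import label_pulse

        inj = clean_config.injected_13c_umol
        for chamber, grp in fluxes.groupby("chamber_id"):
            frac = 0.621 if grp["label_position"].iloc[0] == "C1" else 0.211
            expected = label_pulse(
                grp["closure_time_h"].to_numpy(), clean_config.pulse_shape,
                clean_config.pulse_tau_h, inj * frac, clean_config.collar_area_m2,
            ) / 3600.0
            np.testing.assert_allclose(
                grp["excess13C"].to_numpy(), expected, atol=1e-9, rtol=1e-6
            )
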