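"""Generator-level checks: label mass arithmetic, pulse shape, closure
forward model, bundle structure and ground-truth bookkeeping."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from pyruflux import (
    chamber_flux,
    fticr,
    generate_fticr_peaks,
    generate_plsr_dataset,
    generate_scenario,
    injected_13C_mass,
    label_pulse,
    plsr,
    pulse_cumulative,
    synthetic,
)
from pyruflux.synthetic import closure_from_flux

from conftest import small_config


class TestInjectedMass:
    @pytest.mark.parametrize(
        "mass,mw,npos,expected",
        [
            (100.0, 111.03, 1, 100.0 / 111.03 * 13.0034),  # sodium salt
            (111.03, 111.03, 1, 13.0034),  # exactly one mmol
            (100.0, 89.05, 1, 100.0 / 89.05 * 13.0034),  # free acid
        ],
    )
    def test_mass_arithmetic(self, mass, mw, npos, expected):
        assert injected_13C_mass(mass, mw, npos) == pytest.approx(expected, rel=1e-12)

    def test_headline_values(self):
        assert injected_13C_mass(100.0, 111.03) == pytest.approx(11.71, abs=0.005)
        assert injected_13C_mass(100.0, 89.05) == pytest.approx(14.60, abs=0.005)

    @pytest.mark.parametrize("mass,mw,npos", [(0, 111, 1), (-1, 111, 1), (100, 0, 1), (100, 111, 0)])
    def test_invalid_inputs(self, mass, mw, npos):
        with pytest.raises(ValueError):
            injected_13C_mass(mass, mw, npos)


class TestLabelPulse:
    def test_zero_total_is_zero_everywhere(self):
        t = np.linspace(0, 48, 100)
        assert np.all(label_pulse(t, 1.0, 6.0, 0.0, 0.0318) == 0)

    def test_integral_matches_quadrature(self):
        area = 0.0318
        total = 7.2729  # 11.7116 mg x (0.410 + 0.211), a C1 chamber
        integral, _ = quad(lambda t: label_pulse(t, 1.0, 6.0, total, area), 0, np.inf)
        assert integral * area == pytest.approx(total, rel=1e-8)

    def test_c1_c2_pulse_totals(self):
        inj = injected_13C_mass(100.0, 111.03)
        assert inj * (0.410 + 0.211) == pytest.approx(7.27, abs=0.005)
        assert inj * 0.211 == pytest.approx(2.47, abs=0.005)

    def test_mode_at_shape_times_tau(self):
        t = np.linspace(0, 48, 48001)
        f = label_pulse(t, 1.0, 6.0, 1.0, 1.0)
        assert t[np.argmax(f)] == pytest.approx(6.0, abs=0.01)

    def test_cumulative_is_incomplete_gamma(self):
        # numeric quadrature oracle for the truncated integral
        total, shape, tau = 2.4711, 1.0, 5.0
        num, _ = quad(lambda t: label_pulse(t, shape, tau, total, 1.0), 0, 48)
        assert pulse_cumulative(48.0, shape, tau, total) == pytest.approx(num, rel=1e-8)

    def test_negative_parameters_raise(self):
        with pytest.raises(ValueError):
            label_pulse(1.0, -1.0, 6.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            label_pulse(1.0, 1.0, 6.0, -1.0, 1.0)


class TestClosureForwardModel:
    GEOM = dict(volume_m3=0.004076, area_m2=0.0318, temperature_k=296.15, pressure_pa=101325.0)

    def test_linear_round_trip_through_flux_conversion(self):
        f12, f13 = 3.2, 0.06
        t = np.arange(0.0, 391.0, 2.0)
        x12, x13 = closure_from_flux(f12, f13, c0_12c=415.0, c0_13c=4.6, t_s=t, **self.GEOM)
        for x, f in [(x12, f12), (x13, f13)]:
            slope = np.polyfit(t, x, 1)[0]
            recovered = chamber_flux.mole_fraction_slope_to_flux(
                slope, self.GEOM["volume_m3"], self.GEOM["area_m2"],
                self.GEOM["temperature_k"], self.GEOM["pressure_pa"],
            )
            assert recovered == pytest.approx(f, rel=1e-9)

    def test_zero_flux_constant_series(self):
        t = np.arange(0.0, 391.0, 2.0)
        x12, x13 = closure_from_flux(0.0, 0.0, c0_12c=415.0, c0_13c=4.6, t_s=t, **self.GEOM)
        assert np.all(x12 == 415.0) and np.all(x13 == 4.6)

    def test_negative_sigma_raises(self):
        with pytest.raises(ValueError):
            closure_from_flux(1.0, 0.01, c0_12c=400, c0_13c=4, t_s=np.arange(10.0),
                              sigma_12c=-1.0, **self.GEOM)


class TestGenerateScenario:
    def test_structure_and_determinism(self):
        config = small_config(sigma_x12_umol_mol=0.05, sigma_x13_umol_mol=0.005,
                              sigma_voc_nmol_mol=0.02, chamber_scale_sd=0.08)
        b1 = generate_scenario(config, seed=7)
        b2 = generate_scenario(config, seed=7)
        pd.testing.assert_frame_equal(b1["closures"], b2["closures"])
        pd.testing.assert_frame_equal(b1["voc_closures"], b2["voc_closures"])
        assert b1["closures"]["chamber_id"].nunique() == 2  # one C1/C2 pair
        assert set(b1["pairing"].columns) == {"site", "pair_id", "c1_chamber", "c2_chamber"}
        n_closures = len(config.closure_start_times_h())
        assert b1["closures"].groupby("chamber_id")["closure_index"].nunique().eq(n_closures).all()

    def test_full_design_has_18_chambers(self):
        config = small_config(n_sites=3, replicates_per_site=3,
                              closure_cadence_s=100.0, voc_cadence_s=30.0)
        bundle = generate_scenario(config, seed=0)
        assert bundle["closures"]["chamber_id"].nunique() == 18
        assert len(bundle["pairing"]) == 9

    def test_truth_cumulative_is_truncated_pulse_integral(self, clean_config):
        bundle = generate_scenario(clean_config, seed=3)
        truth = bundle["truth"]
        inj = clean_config.injected_13c_mg
        for chamber, rec in truth.chambers.items():
            frac = 0.621 if rec["label_position"] == "C1" else 0.211
            assert rec["pulse_total_13c_mg"] == pytest.approx(inj * frac, rel=1e-9)
            expected = pulse_cumulative(
                48.0, rec["pulse_shape"], rec["pulse_tau_h"], rec["pulse_total_13c_mg"]
            )
            assert rec["cum_13c_mg_48h"] == pytest.approx(expected, rel=1e-9)
            assert rec["cum_13c_mg_48h"] <= inj  # conservation

    def test_lower_baseline_flux_gives_smaller_co2_rise(self):
        wet = small_config(baseline_co2_flux=4.0)
        dry = small_config(baseline_co2_flux=2.0)
        rise = {}
        for name, config in [("wet", wet), ("dry", dry)]:
            df = generate_scenario(config, seed=5)["closures"]
            total = df["x12C_umol_mol"] + df["x13C_umol_mol"]
            per = df.assign(total=total).groupby(["chamber_id", "closure_index"])["total"]
            rise[name] = (per.last() - per.first()).mean()
        assert rise["dry"] < rise["wet"]


class TestFticrGenerator:
    def test_pure_lipid_proportions_round_trip(self):
        peaks = generate_fticr_peaks({"lipid": 1.0}, n_peaks=50, seed=11)
        assigned, profile = fticr.process_peaks(peaks)
        assert len(assigned) == 50
        assert (assigned["compound_class"] == "lipid").all()
        row = profile.set_index("compound_class")["relative_abundance"]
        assert row["lipid"] == pytest.approx(1.0)

    def test_empty_request(self):
        assert generate_fticr_peaks({"lipid": 1.0}, n_peaks=0, seed=0).empty

    def test_low_sn_fraction_is_filtered(self):
        peaks = generate_fticr_peaks({"lignin": 1.0}, n_peaks=50, seed=21, frac_low_sn=0.2)
        n_low = (peaks.groupby("peak_id")["sn"].first() <= 7.0).sum()
        assert n_low > 0  # the configured 20% materialized for this seed
        retained = fticr.filter_peaks(peaks)
        assert retained["peak_id"].nunique() == 50 - n_low

    def test_bad_proportions_raise(self):
        with pytest.raises(ValueError):
            generate_fticr_peaks({"lipid": 0.5}, n_peaks=10, seed=0)


class TestPlsrGenerator:
    def test_noise_free_response_fully_explained_within_rank(self):
        x, y, truth = generate_plsr_dataset(18, 5, active_set=(2,), coefficients=(1.5,), noise_sd=0.0, seed=4)
        fit = plsr.fit_plsr(x, y, 5)
        assert fit.r2_total == pytest.approx(1.0, abs=1e-9)
        assert truth["beta"][2] == 1.5
        # a single predictor carrying the response is captured by 1 component
        x1 = x[["x2"]]
        assert plsr.fit_plsr(x1, y, 1).r2_total == pytest.approx(1.0, abs=1e-9)

    def test_shape_and_mismatched_args(self):
        x, y, _ = generate_plsr_dataset(12, 7, seed=0)
        assert x.shape == (12, 7) and len(y) == 12
        with pytest.raises(ValueError):
            generate_plsr_dataset(10, 5, active_set=(0,), coefficients=(), seed=0)


def test_natural_abundance_constant():
    acetone = synthetic.VocCompoundConfig(formula="C3H6O", carbon_count=3, f_voc_of_bio=0.0)
    assert acetone.natural_13c_fraction == pytest.approx(1 - (1 - 0.011056) ** 3, rel=1e-12)


def test_config_validation_rejects_bad_fractions():
    with pytest.raises(ValueError):
        small_config(allocation_truth={"f_bio": 0.5, "f_tca": 0.3, "f_other": 0.3})
    with pytest.raises(ValueError):
        small_config(n_sites=0)
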