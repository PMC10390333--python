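"""Shared fixtures: reduced scenario configurations for fast pipeline tests."""

from __future__ import annotations

import pytest

from pyruflux import ScenarioConfig


def small_config(**overrides) -> ScenarioConfig:
    """A down-scaled campaign (1 site, 1 chamber pair, coarse schedule).

    Defaults are deterministic (no noise, no per-chamber variability, linear
    closures) so round-trip tests can assert tight tolerances; individual
    tests override what they need.
    """
    base = dict(
        condition="pre_drought",
        n_sites=1,
        replicates_per_site=1,
        baseline_co2_flux=4.0,
        voc_truth={
            "acetone": {
                "formula": "C3H6O",
                "carbon_count": 3,
                "f_voc_of_bio": 2.3e-5,
                "tau_h": 8.0,
                "baseline_flux_nmol_m2_s": 0.05,
                "baseline_conc_nmol_mol": 2.0,
            },
        },
        chamber_scale_sd=0.0,
        baseline_scale_sd=0.0,
        closure_curvature_per_s=0.0,
        sigma_x12_umol_mol=0.0,
        sigma_x13_umol_mol=0.0,
        sigma_voc_nmol_mol=0.0,
        closure_cadence_s=5.0,
        fast_spacing_h=0.75,
        slow_spacing_h=1.0,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture
def clean_config() -> ScenarioConfig:
    return small_config()
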