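"""Convenience drivers chaining the pipeline stages on a scenario."""

from __future__ import annotations

from . import allocation, chamber_flux, synthetic, voc_flux
from .synthetic import ScenarioConfig

__all__ = ["run_scenario", "drought_response"]


def run_scenario(config: ScenarioConfig | str, seed: int) -> dict:
    """simulate -> flux -> vocflux -> allocate for one condition.

    ``config`` is a :class:`ScenarioConfig` or the name of a packaged
    scenario ("pre_drought" / "drought").  Returns the intermediate tables
    and the :class:`~pyruflux.allocation.AllocationResult`.
    """
    if isinstance(config, str):
        config = synthetic.packaged_scenario(config)
    bundle = synthetic.generate_scenario(config, seed)
    fluxes = chamber_flux.process_closures(bundle["closures"])
    voc_fluxes = voc_flux.process_voc_closures(bundle["voc_closures"])
    result = allocation.scenario_allocation(
        fluxes, voc_fluxes, config.injected_13c_mg, config.collar_area_m2
    )
    return {
        "config": config,
        "truth": bundle["truth"],
        "pairing": bundle["pairing"],
        "fluxes": fluxes,
        "voc_fluxes": voc_fluxes,
        "result": result,
    }


def _position_cums(result, position: str):
    pc = result.per_chamber
    return pc.loc[pc["label_position"] == position, "cum_13c_mg"].to_numpy()


def _voc_cums(result, compound: str, position: str):
    pv = result.per_voc
    sel = (pv["compound"] == compound) & (pv["label_position"] == position)
    return pv.loc[sel, "cum_13c_mg"].to_numpy()


def drought_response(pre: dict, drought: dict) -> dict:
    """Headline drought-response metrics from two ``run_scenario`` outputs.

    Percent decreases of the mean cumulative excess 13C-CO2 per label
    position and drought/pre-drought factors of the cumulative 13C-VOC
    effluxes, computed over chambers of the matching label position.
    """
    pr, dr = pre["result"], drought["result"]
    out = {
        "co2_c1_percent_decrease": allocation.condition_change(
            _position_cums(pr, "C1"), _position_cums(dr, "C1")
        )["percent_decrease"],
        "co2_c2_percent_decrease": allocation.condition_change(
            _position_cums(pr, "C2"), _position_cums(dr, "C2")
        )["percent_decrease"],
    }
    for compound, position, key in [
        ("acetone", "C2", "acetone_c2_factor"),
        ("acetate", "C1", "acetate_c1_factor"),
        ("acetate", "C2", "acetate_c2_factor"),
        ("diacetyl", "C2", "diacetyl_c2_factor"),
    ]:
        out[key] = allocation.condition_change(
            _voc_cums(pr, compound, position), _voc_cums(dr, compound, position)
        )["factor"]
    return out
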