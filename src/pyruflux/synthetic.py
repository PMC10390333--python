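"""Synthetic study-design generator with known ground truth.

Emulates a position-specific 13C-pyruvate soil labelling campaign: paired
chambers at several sites receive pyruvate labelled at either the carboxyl
(C1) or carbonyl (C2) carbon, and automated chambers record CO2 and VOC
isotopologue headspace series for ~48 h.  C1 is released as CO2 during both
biosynthetic decarboxylation and the TCA cycle, while C2 is released only in
the TCA cycle, so the configured allocation fractions fix each chamber's
total label-derived CO2:

    C1 chamber 13C-CO2 out = injected 13C * (f_bio + f_tca)
    C2 chamber 13C-CO2 out = injected 13C * f_tca

Label-derived effluxes follow a gamma-shaped pulse F(t) ~ (t/tau)^s e^(-t/tau)
whose integral over the collar equals the configured total.  VOC 13C pulses
(acetate, acetone, diacetyl+) are configured as fractions of the biosynthesis
pool from C2 chambers, plus an acetogenesis route that puts 13C into acetate
in C1 chambers (acetogens re-fix the 13C-CO2 released by decarboxylation).

Every chamber closure is rendered as a concentration time series through the
exponential headspace-accumulation model (curvature configurable; zero
curvature gives linear accumulation) with i.i.d. Gaussian instrument noise,
so the flux-estimation stages can be validated by round trip against the
analytic truth carried in the :class:`TruthRecord`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import gammainc, gamma as gamma_fn

from .chamber_flux import R_GAS, R_VPDB, MASS_13C_G_MOL

__all__ = [
    "NATURAL_13C_FRACTION",
    "ScenarioConfig",
    "VocCompoundConfig",
    "TruthRecord",
    "injected_13C_mass",
    "label_pulse",
    "pulse_cumulative",
    "closure_from_flux",
    "generate_scenario",
    "generate_fticr_peaks",
    "generate_plsr_dataset",
    "load_scenario",
    "packaged_scenario",
    "write_bundle",
]

#: Natural abundance of 13C (atom fraction) used for background simulation.
NATURAL_13C_FRACTION = 0.011056

#: d13C of ambient air CO2 filling the chamber at closure start, permil.
AMBIENT_DELTA13C = -8.5

#: Ambient CO2 mole fraction at closure start, umol/mol.
AMBIENT_CO2_UMOL_MOL = 420.0


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class VocCompoundConfig:
    """Ground-truth emission behaviour of one 13C-enriched volatile.

    ``f_voc_of_bio`` is the fraction of the biosynthesis 13C pool
    (f_bio * injected 13C) emitted as this 13C-VOC from C2-labelled
    chambers over the whole pulse.  ``c1_acetogenesis_frac`` is the fraction
    of the injected 13C emitted as this 13C-VOC from C1 chambers via
    re-fixation of 13C-CO2 (nonzero only for acetate).
    """

    formula: str
    carbon_count: int
    f_voc_of_bio: float
    c1_acetogenesis_frac: float = 0.0
    tau_h: float = 8.0
    shape: float = 1.0
    baseline_flux_nmol_m2_s: float = 0.05
    baseline_conc_nmol_mol: float = 2.0

    def __post_init__(self) -> None:
        _require(self.carbon_count >= 1, "carbon_count must be >= 1")
        _require(0 <= self.f_voc_of_bio <= 1, "f_voc_of_bio must be in [0,1]")
        _require(0 <= self.c1_acetogenesis_frac <= 1, "c1_acetogenesis_frac must be in [0,1]")
        _require(self.tau_h > 0 and self.shape >= 0, "pulse parameters must be positive")

    @property
    def natural_13c_fraction(self) -> float:
        """Probability that a molecule carries at least one 13C atom.

        Single-labelling approximation: a = 1 - (1 - 0.011056)^nC.
        """
        return 1.0 - (1.0 - NATURAL_13C_FRACTION) ** self.carbon_count


@dataclass
class ScenarioConfig:
    """Full description of one labelling campaign condition."""

    condition: str  # "pre_drought" | "drought"
    n_sites: int = 3
    replicates_per_site: int = 3
    label_positions: tuple[str, ...] = ("C1", "C2")
    injected_pyruvate_mass_mg: float = 100.0
    pyruvate_molar_mass_g_mol: float = 111.03  # sodium [13C]pyruvate
    labelled_positions_per_molecule: int = 1
    collar_area_m2: float = 0.0318
    chamber_volume_m3: float = 0.004076
    air_temperature_k: float = 296.15
    air_pressure_pa: float = 101325.0
    baseline_co2_flux: float = 4.0  # umol m-2 s-1
    baseline_delta13c: float = -25.0  # permil vs VPDB
    allocation_truth: dict = field(
        default_factory=lambda: {"f_bio": 0.41, "f_tca": 0.211, "f_other": 0.379}
    )
    voc_truth: dict = field(default_factory=dict)  # name -> VocCompoundConfig
    # label-pulse shape: F(t) ~ (t/tau)^shape * exp(-t/tau)
    pulse_shape: float = 1.0
    pulse_tau_h: float = 5.0
    #: lognormal sd of the mean-one per-chamber activity multiplier
    chamber_scale_sd: float = 0.08
    #: lognormal sd of the per-chamber baseline-flux multiplier
    baseline_scale_sd: float = 0.10
    # headspace accumulation curvature a (s-1); 0 = linear accumulation
    closure_curvature_per_s: float = 5.0e-5
    # closure schedule
    pre_injection_hours: float = 12.0
    pre_spacing_h: float = 2.0
    fast_until_h: float = 8.0
    fast_spacing_h: float = 0.5
    slow_spacing_h: float = 50.0 / 60.0
    end_h: float = 48.0
    closure_length_s: float = 390.0
    closure_cadence_s: float = 2.0
    voc_cadence_s: float = 10.0
    voc_length_s: float = 150.0
    # measurement noise
    sigma_x12_umol_mol: float = 0.05
    sigma_x13_umol_mol: float = 0.005
    sigma_voc_nmol_mol: float = 0.02
    soil_moisture_mean_pct: float = 26.0
    soil_moisture_sd_pct: float = 6.9

    def __post_init__(self) -> None:
        self.label_positions = tuple(self.label_positions)
        self.voc_truth = {
            name: (v if isinstance(v, VocCompoundConfig) else VocCompoundConfig(**v))
            for name, v in self.voc_truth.items()
        }
        self.validate()

    def validate(self) -> None:
        a = self.allocation_truth
        _require(
            abs(a["f_bio"] + a["f_tca"] + a["f_other"] - 1.0) <= 1e-9,
            "allocation fractions must sum to 1",
        )
        _require(all(0 <= a[k] <= 1 for k in ("f_bio", "f_tca", "f_other")),
                 "allocation fractions must be in [0,1]")
        _require(self.n_sites >= 1 and self.replicates_per_site >= 1,
                 "site and replicate counts must be >= 1")
        _require(self.injected_pyruvate_mass_mg > 0, "injected mass must be positive")
        _require(self.pyruvate_molar_mass_g_mol > 0, "molar mass must be positive")
        _require(self.labelled_positions_per_molecule >= 1,
                 "labelled_positions_per_molecule must be >= 1")
        for s in (self.sigma_x12_umol_mol, self.sigma_x13_umol_mol, self.sigma_voc_nmol_mol):
            _require(s >= 0, "noise sigma must be non-negative")
        _require(set(self.label_positions) <= {"C1", "C2"},
                 "label positions must be C1 and/or C2")
        _require(self.closure_curvature_per_s >= 0, "curvature must be >= 0")

    # -- convenience -------------------------------------------------------

    @property
    def injected_13c_mg(self) -> float:
        return injected_13C_mass(
            self.injected_pyruvate_mass_mg,
            self.pyruvate_molar_mass_g_mol,
            self.labelled_positions_per_molecule,
        )

    @property
    def injected_13c_umol(self) -> float:
        return self.injected_13c_mg / MASS_13C_G_MOL * 1000.0

    def closure_start_times_h(self) -> np.ndarray:
        pre = np.arange(-self.pre_injection_hours, 0.0, self.pre_spacing_h)
        fast = np.arange(0.0, self.fast_until_h, self.fast_spacing_h)
        slow = np.arange(self.fast_until_h, self.end_h + 1e-9, self.slow_spacing_h)
        return np.concatenate([pre, fast, slow])

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["label_positions"] = list(self.label_positions)
        return d


@dataclass
class TruthRecord:
    """Analytic ground truth carried alongside a generated bundle."""

    seed: int
    condition: str
    injected_13c_mg: float
    allocation_truth: dict
    #: chamber_id -> {"pulse_total_13c_mg", "cum_13c_mg_48h", "scale"}
    chambers: dict
    #: compound -> {chamber_id -> {"pulse_total_13c_nmol", "cum_13c_nmol_48h"}}
    voc: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def injected_13C_mass(
    mass_mg: float, molar_mass_g_mol: float, labelled_positions: int = 1
) -> float:
    """mg of 13C injected with ``mass_mg`` of a singly/multiply labelled compound.

    The stated mass is the mass of the labelled compound itself:
    mg 13C = mass / M * labelled_positions * 13.0034.
    """
    if mass_mg <= 0 or molar_mass_g_mol <= 0:
        raise ValueError("mass and molar mass must be positive")
    if labelled_positions < 1:
        raise ValueError("labelled_positions must be >= 1")
    return mass_mg / molar_mass_g_mol * labelled_positions * MASS_13C_G_MOL


def label_pulse(
    t_hours: np.ndarray | float,
    shape: float,
    tau_h: float,
    total_13c_out: float,
    collar_area_m2: float,
) -> np.ndarray | float:
    """Gamma-shaped label efflux (amount m-2 h-1) at times ``t_hours``.

    F(t) = A (t/tau)^shape exp(-t/tau), with A chosen so that the integral
    over [0, inf) times the collar area equals ``total_13c_out`` (any amount
    unit; the flux is in that unit per m2 per h).  t < 0 gives 0.
    """
    if shape < 0 or tau_h <= 0 or collar_area_m2 <= 0:
        raise ValueError("pulse parameters must be positive")
    if total_13c_out < 0:
        raise ValueError("total_13c_out must be >= 0")
    t = np.asarray(t_hours, dtype=float)
    amp = total_13c_out / (collar_area_m2 * tau_h * gamma_fn(shape + 1.0))
    x = np.where(t > 0, t / tau_h, 0.0)
    out = np.where(t > 0, amp * x**shape * np.exp(-x), 0.0)
    return out if out.ndim else float(out)


def pulse_cumulative(
    t_hours: float, shape: float, tau_h: float, total_13c_out: float
) -> float:
    """Analytic integral of the pulse from 0 to ``t_hours`` (whole collar).

    Regularized lower incomplete gamma: total * P(shape+1, t/tau).
    """
    if t_hours <= 0:
        return 0.0
    return total_13c_out * float(gammainc(shape + 1.0, t_hours / tau_h))


def closure_from_flux(
    f_12c: float,
    f_13c: float,
    volume_m3: float,
    area_m2: float,
    temperature_k: float,
    pressure_pa: float,
    c0_12c: float,
    c0_13c: float,
    t_s: np.ndarray,
    sigma_12c: float = 0.0,
    sigma_13c: float = 0.0,
    curvature_per_s: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-model one closure's isotopologue mole-fraction series.

    The headspace follows C(t) = Cs + (C0 - Cs) exp(-a t) whose initial
    slope equals the supplied flux through the ideal-gas conversion
    (slope = F R T A / (P V)); a -> 0 gives linear accumulation.  Gaussian
    noise of the given sigmas is added per channel.
    """
    if sigma_12c < 0 or sigma_13c < 0:
        raise ValueError("noise sigma must be non-negative")
    if curvature_per_s < 0:
        raise ValueError("curvature must be non-negative")
    t = np.asarray(t_s, dtype=float)
    conv = R_GAS * temperature_k * area_m2 / (pressure_pa * volume_m3)
    s12 = f_12c * conv  # umol mol-1 s-1
    s13 = f_13c * conv
    a = curvature_per_s
    if a > 0:
        ramp = -np.expm1(-a * t) / a  # -> t as a -> 0
    else:
        ramp = t
    x12 = c0_12c + s12 * ramp
    x13 = c0_13c + s13 * ramp
    if rng is not None and (sigma_12c > 0 or sigma_13c > 0):
        x12 = x12 + rng.normal(0.0, sigma_12c, size=t.shape)
        x13 = x13 + rng.normal(0.0, sigma_13c, size=t.shape)
    return np.clip(x12, 0.0, None), np.clip(x13, 0.0, None)


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------

def _delta_to_13c_fraction(delta_permil: float) -> float:
    r = R_VPDB * (1.0 + delta_permil / 1000.0)
    return r / (1.0 + r)


def generate_scenario(config: ScenarioConfig, seed: int) -> dict:
    """Generate the full dataset bundle for one condition.

    Returns ``{"closures": DataFrame, "voc_closures": DataFrame,
    "pairing": DataFrame, "truth": TruthRecord}``.  All randomness flows
    from ``seed``; identical config + seed give identical bundles.
    """
    rng = np.random.default_rng(seed)
    inj_umol = config.injected_13c_umol
    a_truth = config.allocation_truth
    times_h = config.closure_start_times_h()
    t_closure = np.arange(0.0, config.closure_length_s + 1e-9, config.closure_cadence_s)
    t_voc = np.arange(0.0, config.voc_length_s + 1e-9, config.voc_cadence_s)
    xf_base = _delta_to_13c_fraction(config.baseline_delta13c)
    xf_amb = _delta_to_13c_fraction(AMBIENT_DELTA13C)

    co2_frames: list[pd.DataFrame] = []
    voc_frames: list[pd.DataFrame] = []
    pairing_rows: list[dict] = []
    truth_chambers: dict = {}
    truth_voc: dict = {name: {} for name in config.voc_truth}

    for site in range(1, config.n_sites + 1):
        for rep in range(1, config.replicates_per_site + 1):
            pair = {}
            for pos in config.label_positions:
                chamber = f"S{site}{pos}R{rep}"
                pair[pos] = chamber
                scale = float(rng.lognormal(
                    -0.5 * config.chamber_scale_sd**2, config.chamber_scale_sd
                ))
                base_scale = float(rng.lognormal(
                    -0.5 * config.baseline_scale_sd**2, config.baseline_scale_sd
                ))
                f_base = config.baseline_co2_flux * base_scale
                if pos == "C1":
                    total_umol = inj_umol * (a_truth["f_bio"] + a_truth["f_tca"]) * scale
                else:
                    total_umol = inj_umol * a_truth["f_tca"] * scale
                truth_chambers[chamber] = {
                    "label_position": pos,
                    "site": site,
                    "scale": scale,
                    "pulse_total_13c_mg": total_umol * MASS_13C_G_MOL / 1000.0,
                    "cum_13c_mg_48h": pulse_cumulative(
                        config.end_h, config.pulse_shape, config.pulse_tau_h,
                        total_umol,
                    ) * MASS_13C_G_MOL / 1000.0,
                    "pulse_shape": config.pulse_shape,
                    "pulse_tau_h": config.pulse_tau_h,
                }

                # --- CO2 closures ---
                excess = label_pulse(
                    times_h, config.pulse_shape, config.pulse_tau_h,
                    total_umol, config.collar_area_m2,
                ) / 3600.0  # umol m-2 s-1
                f12_base = f_base * (1.0 - xf_base)
                f13_base = f_base * xf_base
                n_t = len(t_closure)
                for ci, (t0_h, f13x) in enumerate(zip(times_h, excess)):
                    x12, x13 = closure_from_flux(
                        f12_base,
                        f13_base + f13x,
                        config.chamber_volume_m3,
                        config.collar_area_m2,
                        config.air_temperature_k,
                        config.air_pressure_pa,
                        AMBIENT_CO2_UMOL_MOL * (1.0 - xf_amb),
                        AMBIENT_CO2_UMOL_MOL * xf_amb,
                        t_closure,
                        config.sigma_x12_umol_mol,
                        config.sigma_x13_umol_mol,
                        config.closure_curvature_per_s,
                        rng,
                    )
                    co2_frames.append(pd.DataFrame({
                        "chamber_id": chamber,
                        "site": f"S{site}",
                        "label_position": pos,
                        "condition": config.condition,
                        "closure_index": ci,
                        "closure_time_h": t0_h,
                        "t_s": t_closure,
                        "x12C_umol_mol": x12,
                        "x13C_umol_mol": x13,
                        "chamber_volume_m3": config.chamber_volume_m3,
                        "collar_area_m2": config.collar_area_m2,
                        "air_temperature_K": config.air_temperature_k,
                        "air_pressure_Pa": config.air_pressure_pa,
                    }))

                # --- VOC closures ---
                for name, voc in config.voc_truth.items():
                    if pos == "C2":
                        voc_total_nmol = (
                            voc.f_voc_of_bio * a_truth["f_bio"] * inj_umol * 1000.0 * scale
                        )
                    else:
                        voc_total_nmol = voc.c1_acetogenesis_frac * inj_umol * 1000.0 * scale
                    truth_voc[name][chamber] = {
                        "pulse_total_13c_nmol": voc_total_nmol,
                        "cum_13c_nmol_48h": pulse_cumulative(
                            config.end_h, voc.shape, voc.tau_h, voc_total_nmol
                        ),
                    }
                    excess_voc = label_pulse(
                        times_h, voc.shape, voc.tau_h, voc_total_nmol,
                        config.collar_area_m2,
                    ) / 3600.0  # nmol m-2 s-1
                    a_nat = voc.natural_13c_fraction
                    fb = voc.baseline_flux_nmol_m2_s * base_scale
                    for ci, (t0_h, f13x) in enumerate(zip(times_h, excess_voc)):
                        c12, c13 = closure_from_flux(
                            fb * (1.0 - a_nat),
                            fb * a_nat + f13x,
                            config.chamber_volume_m3,
                            config.collar_area_m2,
                            config.air_temperature_k,
                            config.air_pressure_pa,
                            voc.baseline_conc_nmol_mol * (1.0 - a_nat),
                            voc.baseline_conc_nmol_mol * a_nat,
                            t_voc,
                            config.sigma_voc_nmol_mol,
                            config.sigma_voc_nmol_mol * a_nat,
                            0.0,  # VOC accumulation rendered linear
                            rng,
                        )
                        voc_frames.append(pd.DataFrame({
                            "compound": name,
                            "formula": voc.formula,
                            "carbon_count": voc.carbon_count,
                            "chamber_id": chamber,
                            "site": f"S{site}",
                            "label_position": pos,
                            "condition": config.condition,
                            "closure_index": ci,
                            "closure_time_h": t0_h,
                            "t_s": t_voc,
                            "c12_nmol_mol": c12,
                            "c13_nmol_mol": c13,
                            "chamber_volume_m3": config.chamber_volume_m3,
                            "collar_area_m2": config.collar_area_m2,
                            "air_temperature_K": config.air_temperature_k,
                            "air_pressure_Pa": config.air_pressure_pa,
                        }))
            if len(pair) == 2:
                pairing_rows.append({
                    "site": f"S{site}",
                    "pair_id": f"S{site}P{rep}",
                    "c1_chamber": pair["C1"],
                    "c2_chamber": pair["C2"],
                })

    truth = TruthRecord(
        seed=seed,
        condition=config.condition,
        injected_13c_mg=config.injected_13c_mg,
        allocation_truth=dict(a_truth),
        chambers=truth_chambers,
        voc=truth_voc,
    )
    return {
        "closures": pd.concat(co2_frames, ignore_index=True),
        "voc_closures": pd.concat(voc_frames, ignore_index=True),
        "pairing": pd.DataFrame(pairing_rows),
        "truth": truth,
    }


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    """Write a generated bundle as CSV files + truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["closures"].to_csv(out / "closures.csv", index=False)
    bundle["voc_closures"].to_csv(out / "voc_closures.csv", index=False)
    bundle["pairing"].to_csv(out / "pairing.csv", index=False)
    bundle["truth"].to_json(out / "truth.json")


# ---------------------------------------------------------------------------
# FTICR peak-list generation
# ---------------------------------------------------------------------------

# interior sampling boxes (O:C lo/hi, H:C lo/hi), shrunk from the printed
# class boundaries so rounding of integer element counts cannot cross a box
# edge; classification itself lives in the fticr module.
_CLASS_INTERIORS = {
    "lipid": (0.15, 0.29, 1.6, 2.4),
    "unsaturated_hydrocarbon": (0.0, 0.11, 0.9, 1.4),
    "protein": (0.32, 0.53, 1.6, 2.2),
    "amino_sugar": (0.57, 0.69, 1.6, 2.1),
    "lignin": (0.2, 0.6, 0.9, 1.4),
    "tannin": (0.7, 1.05, 0.9, 1.4),
    "condensed_hydrocarbon": (0.05, 0.9, 0.3, 0.7),
}


def generate_fticr_peaks(
    class_proportions: dict[str, float],
    n_peaks: int,
    seed: int,
    frac_low_sn: float = 0.0,
    frac_bad_error: float = 0.0,
    decoy_rate: float = 0.2,
) -> pd.DataFrame:
    """Synthetic FTICR peak list with candidate formulas, one row per candidate.

    Each peak's primary formula has O:C and H:C strictly inside the requested
    van Krevelen class box.  ``frac_low_sn`` of peaks get S/N <= 7 and
    ``frac_bad_error`` get no candidate below 1 ppm, so a configured fraction
    fails the assignment filters; ``decoy_rate`` of peaks carry an extra
    worse candidate to exercise formula selection.
    """
    if n_peaks < 0:
        raise ValueError("n_peaks must be >= 0")
    total = sum(class_proportions.values())
    if n_peaks > 0 and abs(total - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    unknown = set(class_proportions) - set(_CLASS_INTERIORS)
    if unknown:
        raise ValueError(f"unknown classes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    names = list(class_proportions)
    probs = np.array([class_proportions[n] for n in names], dtype=float)
    rows: list[dict] = []
    for pid in range(n_peaks):
        cls = names[rng.choice(len(names), p=probs)] if names else "lignin"
        oc_lo, oc_hi, hc_lo, hc_hi = _CLASS_INTERIORS[cls]
        for _attempt in range(200):
            c = int(rng.integers(10, 31))
            o_choices = np.arange(math.ceil(oc_lo * c), math.floor(oc_hi * c) + 1)
            h_choices = np.arange(math.ceil(hc_lo * c), math.floor(hc_hi * c) + 1)
            o_choices = o_choices[o_choices >= 0]
            h_choices = h_choices[h_choices >= 1]
            if len(o_choices) and len(h_choices):
                o = int(rng.choice(o_choices))
                h = int(rng.choice(h_choices))
                break
        else:  # pragma: no cover - interiors always admit integer counts
            raise RuntimeError("failed to sample a formula inside the class box")
        formula = f"C{c}H{h}" + (f"O{o}" if o > 0 else "")
        mz = 12.0 * c + 1.007825 * h + 15.994915 * o + 1.007276  # [M+H]+ approx
        sn = float(rng.uniform(1.0, 7.0)) if rng.random() < frac_low_sn else float(rng.uniform(8.0, 100.0))
        if rng.random() < frac_bad_error:
            err = float(rng.uniform(1.1, 5.0)) * (1 if rng.random() < 0.5 else -1)
        else:
            err = float(np.clip(rng.normal(0.0, 0.3), -0.95, 0.95))
        intensity = float(rng.lognormal(10.0, 1.0))
        rows.append({
            "peak_id": pid, "mz": mz, "intensity": intensity, "sn": sn,
            "candidate_formula": formula, "error_ppm": err,
        })
        if rng.random() < decoy_rate:
            # a worse candidate: higher |error| and an extra heteroatom
            decoy = f"C{c}H{h}" + (f"O{o}" if o > 0 else "") + "N1"
            rows.append({
                "peak_id": pid, "mz": mz, "intensity": intensity, "sn": sn,
                "candidate_formula": decoy,
                "error_ppm": float(np.clip(abs(err) + rng.uniform(0.05, 0.5), None, 0.99))
                * (1 if rng.random() < 0.5 else -1),
            })
    return pd.DataFrame(
        rows, columns=["peak_id", "mz", "intensity", "sn", "candidate_formula", "error_ppm"]
    )


# ---------------------------------------------------------------------------
# PLSR driver-analysis table generation
# ---------------------------------------------------------------------------

def generate_plsr_dataset(
    n: int,
    p: int,
    active_set: list[int] | tuple[int, ...] = (),
    coefficients: list[float] | tuple[float, ...] = (),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Gaussian predictor table and linear response with known coefficients.

    X ~ N(0,1) (n x p); y = X beta + eps with beta nonzero only on
    ``active_set``.  Returns (X, y, truth) where truth carries beta.
    """
    if len(active_set) != len(coefficients):
        raise ValueError("active_set and coefficients must have equal length")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    beta = np.zeros(p)
    for j, b in zip(active_set, coefficients):
        beta[j] = b
    y = x @ beta + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    cols = [f"x{j}" for j in range(p)]
    return (
        pd.DataFrame(x, columns=cols),
        pd.Series(y, name="y"),
        {"beta": beta.tolist(), "active_set": list(active_set), "seed": seed},
    )


# ---------------------------------------------------------------------------
# Scenario configuration I/O
# ---------------------------------------------------------------------------

def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load a scenario configuration from a YAML file."""
    with open(path) as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh))


def packaged_scenario(name: str) -> ScenarioConfig:
    """Load one of the packaged scenarios ("pre_drought" or "drought")."""
    ref = resources.files("pyruflux") / "scenarios" / f"{name}.yaml"
    return ScenarioConfig.from_dict(yaml.safe_load(ref.read_text()))
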