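"""13C fractional abundance and 13C fluxes of volatile metabolites.

PTR-type instruments report the 12C and 13C isotopologue concentrations of a
volatile per 10 s sample during a chamber closure.  The label signal is the
rate of change of the 13C fractional abundance a = c13/(c12 + c13) over the
10 samples following a 30 s mixing deadband; the 13C mass flux needed for
cumulative label budgets is the OLS slope of the c13 channel over the same
window, converted to an areal flux and corrected for the natural-abundance
contribution of the compound's baseline emission.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chamber_flux import mole_fraction_slope_to_flux

__all__ = [
    "fractional_abundance",
    "enrichment_slope",
    "voc_13C_flux",
    "process_voc_closures",
]

DEFAULT_DEADBAND_S = 30.0
DEFAULT_N_POINTS = 10


def fractional_abundance(c12: np.ndarray | float, c13: np.ndarray | float) -> np.ndarray | float:
    """13C fractional abundance a = c13 / (c12 + c13); nan where the total is 0."""
    c12 = np.asarray(c12, dtype=float)
    c13 = np.asarray(c13, dtype=float)
    total = c12 + c13
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(total > 0, c13 / total, np.nan)
    return a if a.ndim else float(a)


def _window(t_s: np.ndarray, deadband_s: float, n_points: int) -> np.ndarray:
    idx = np.flatnonzero(np.asarray(t_s, dtype=float) >= deadband_s)
    if len(idx) < n_points:
        raise ValueError(
            f"need >= {n_points} samples after the {deadband_s} s deadband, "
            f"got {len(idx)}"
        )
    return idx[:n_points]


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(t, y, 1)[0])


def enrichment_slope(
    t_s: np.ndarray,
    c12: np.ndarray,
    c13: np.ndarray,
    deadband_s: float = DEFAULT_DEADBAND_S,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """da/dt (s-1): OLS slope of the 13C fractional abundance over exactly
    the first ``n_points`` post-deadband samples."""
    idx = _window(t_s, deadband_s, n_points)
    a = fractional_abundance(np.asarray(c12)[idx], np.asarray(c13)[idx])
    return _ols_slope(np.asarray(t_s, dtype=float)[idx], a)


def voc_13C_flux(
    t_s: np.ndarray,
    c12: np.ndarray,
    c13: np.ndarray,
    volume_m3: float,
    area_m2: float,
    temperature_k: float,
    pressure_pa: float,
    baseline_abundance: float = 0.0,
    deadband_s: float = DEFAULT_DEADBAND_S,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """Excess 13C-VOC flux (same amount unit as the concentrations, m-2 s-1).

    OLS slope of the c13 channel over the 10-point window, converted through
    the ideal-gas chamber relation, then corrected for the natural-abundance
    share of the total emission: with baseline fractional abundance a_b and
    total flux F_tot, the unlabelled emission contributes a_b (F_tot - F_x)
    to the 13C channel, so the excess solves

        F_x = (F13 - a_b * F_tot) / (1 - a_b).

    With ``baseline_abundance=0`` this is the raw 13C-VOC flux.
    """
    idx = _window(t_s, deadband_s, n_points)
    t = np.asarray(t_s, dtype=float)[idx]
    s13 = _ols_slope(t, np.asarray(c13, dtype=float)[idx])
    f13 = mole_fraction_slope_to_flux(s13, volume_m3, area_m2, temperature_k, pressure_pa)
    if baseline_abundance > 0:
        s_tot = _ols_slope(
            t, np.asarray(c12, dtype=float)[idx] + np.asarray(c13, dtype=float)[idx]
        )
        f_tot = mole_fraction_slope_to_flux(
            s_tot, volume_m3, area_m2, temperature_k, pressure_pa
        )
        f13 = (f13 - baseline_abundance * f_tot) / (1.0 - baseline_abundance)
    return f13


def process_voc_closures(
    voc_closures: pd.DataFrame,
    deadband_s: float = DEFAULT_DEADBAND_S,
    n_points: int = DEFAULT_N_POINTS,
    baseline_window_h: float = 12.0,
) -> pd.DataFrame:
    """Per-closure VOC enrichment and excess 13C flux for every compound.

    Expects the long-format voc_closures table produced by the generator
    (or equivalent CSV).  The baseline fractional abundance of each
    chamber x compound is the mean closure-level abundance over the
    pre-injection window; the excess 13C flux of every closure subtracts
    the natural-abundance share implied by that baseline.  Excess fluxes
    are deliberately not floored at zero so that measurement noise averages
    out of cumulative budgets.
    """
    rows = []
    group_cols = ["compound", "chamber_id", "closure_index"]
    for (compound, chamber, ci), grp in voc_closures.groupby(group_cols, sort=True, observed=True):
        grp = grp.sort_values("t_s")
        first = grp.iloc[0]
        t = grp["t_s"].to_numpy()
        c12 = grp["c12_nmol_mol"].to_numpy()
        c13 = grp["c13_nmol_mol"].to_numpy()
        try:
            idx = _window(t, deadband_s, n_points)
        except ValueError:
            rows.append({
                "compound": compound, "chamber_id": chamber,
                "site": first["site"], "label_position": first["label_position"],
                "condition": first["condition"],
                "closure_time_h": float(first["closure_time_h"]),
                "a_mean": np.nan, "da_dt": np.nan,
                "F13C_voc_raw": np.nan, "qc_flag": "insufficient_data",
            })
            continue
        a = fractional_abundance(c12[idx], c13[idx])
        rows.append({
            "compound": compound,
            "chamber_id": chamber,
            "site": first["site"],
            "label_position": first["label_position"],
            "condition": first["condition"],
            "closure_time_h": float(first["closure_time_h"]),
            "a_mean": float(np.nanmean(a)),
            "da_dt": enrichment_slope(t, c12, c13, deadband_s, n_points),
            "F13C_voc_raw": voc_13C_flux(
                t, c12, c13,
                float(first["chamber_volume_m3"]),
                float(first["collar_area_m2"]),
                float(first["air_temperature_K"]),
                float(first["air_pressure_Pa"]),
                baseline_abundance=0.0,
                deadband_s=deadband_s,
                n_points=n_points,
            ),
            "F_total_voc": voc_13C_flux(
                t, c13, c12,  # swapped: slope of c12 channel
                float(first["chamber_volume_m3"]),
                float(first["collar_area_m2"]),
                float(first["air_temperature_K"]),
                float(first["air_pressure_Pa"]),
                baseline_abundance=0.0,
                deadband_s=deadband_s,
                n_points=n_points,
            ),
            "qc_flag": "ok",
        })
    out = pd.DataFrame(rows)
    # F_total_voc currently holds the c12 slope flux; total = c12 + c13
    out["F_total_voc"] = out["F_total_voc"] + out["F13C_voc_raw"]

    pre = out[(out["closure_time_h"] < 0) & (out["closure_time_h"] >= -baseline_window_h)]
    baselines = pre.groupby(["compound", "chamber_id"], observed=True)["a_mean"].mean()
    key = pd.MultiIndex.from_frame(out[["compound", "chamber_id"]])
    out["baseline_a"] = baselines.reindex(key).to_numpy()
    a_b = out["baseline_a"].fillna(0.0)
    out["F13C_voc"] = (out["F13C_voc_raw"] - a_b * out["F_total_voc"]) / (1.0 - a_b)
    return out
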