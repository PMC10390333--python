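"""Per-closure soil CO2 flux estimation from chamber headspace time series.

An automated chamber seals onto a soil collar and the headspace CO2 mole
fraction is recorded while the chamber is closed (6.5 min of usable data per
closure).  The soil efflux is recovered from the accumulation rate: a linear
fit over the first 120 s after a 30 s mixing deadband, and an exponential
closure model ``C(t) = Cs + (C0 - Cs) exp(-a t)`` over the full closure,
whose initial slope ``a (Cs - C0)`` defines the flux.  The exponential fit is
preferred when it converges and is not materially worse than the line;
otherwise the linear flux is used.

The analyser reports the 12C-CO2 and 13C-CO2 isotopologues separately; their
individual 120 s linear fits give isotopologue fluxes, whose ratio yields the
d13C of the efflux on the VPDB scale.  The excess (label-derived) 13C flux is
the 13C flux above what the chamber's own pre-injection isotopic baseline
predicts from the 12C flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "R_VPDB",
    "R_GAS",
    "MASS_13C_G_MOL",
    "ClosureSeries",
    "FluxEstimate",
    "apply_deadband",
    "mole_fraction_slope_to_flux",
    "fit_linear",
    "fit_exponential",
    "select_flux",
    "isotopologue_fluxes",
    "delta13C_from_fluxes",
    "excess_13C_flux",
    "process_closures",
]

#: 13C/12C isotope ratio of the Vienna Pee Dee Belemnite standard.
R_VPDB = 0.0111802

#: Ideal gas constant, J mol-1 K-1.
R_GAS = 8.314

#: Molar mass of 13C, g mol-1 (equivalently ug umol-1).
MASS_13C_G_MOL = 13.0034

#: Default deadband (s) discarded at the start of each closure for mixing.
DEFAULT_DEADBAND_S = 30.0

#: Default window (s) for the linear fits, counted after the deadband.
DEFAULT_LINEAR_WINDOW_S = 120.0

#: Exponential flux is accepted if its R2 is within this margin of the line.
R2_MARGIN = 0.05

#: |residual|/scale threshold above which a closure's flux is rejected.
OUTLIER_Z = 4.0


@dataclass
class ClosureSeries:
    """One chamber closure: timestamped isotopologue mole fractions.

    ``t_rel`` is seconds since the closure started, strictly increasing.
    Mole fractions are dry-air umol/mol as reported by the analyser.
    """

    chamber_id: str
    site: str
    label_position: str  # "C1" | "C2" | "none"
    condition: str
    closure_time_h: float  # closure start, hours since label injection
    t_rel: np.ndarray
    x12c: np.ndarray
    x13c: np.ndarray
    chamber_volume_m3: float
    collar_area_m2: float
    air_temperature_k: float
    air_pressure_pa: float

    def __post_init__(self) -> None:
        self.t_rel = np.asarray(self.t_rel, dtype=float)
        self.x12c = np.asarray(self.x12c, dtype=float)
        self.x13c = np.asarray(self.x13c, dtype=float)
        if self.t_rel.size == 0:
            raise ValueError("closure series is empty")
        if not (len(self.t_rel) == len(self.x12c) == len(self.x13c)):
            raise ValueError("sample arrays have unequal lengths")
        if np.any(np.diff(self.t_rel) <= 0):
            raise ValueError("t_rel must be strictly increasing")
        if np.any(self.x12c < 0) or np.any(self.x13c < 0):
            raise ValueError("mole fractions must be non-negative")

    @property
    def x_total(self) -> np.ndarray:
        return self.x12c + self.x13c


@dataclass
class FitResult:
    """Outcome of a single (linear or exponential) accumulation fit."""

    slope: float  # initial mole-fraction rate, umol mol-1 s-1
    r2: float
    residual_sd: float
    converged: bool
    method: str  # "linear" | "exponential"
    params: dict = field(default_factory=dict)


@dataclass
class FluxEstimate:
    """Per-closure fluxes (umol m-2 s-1), d13C and QC information."""

    f_total: float
    f_12c: float
    f_13c: float
    delta13c: float  # permil vs VPDB; nan when undefined
    excess_13c: float  # umol 13C m-2 s-1 above the chamber baseline
    fit_method: str  # "linear" | "exponential"
    r2: float
    residual_sd: float
    exp_rate: float  # exponential rate a (s-1); nan for linear
    qc_flag: str  # "ok" | "replaced_by_linear" | "rejected"


def apply_deadband(series: ClosureSeries, deadband_s: float = DEFAULT_DEADBAND_S) -> ClosureSeries:
    """Drop samples inside the mixing deadband and re-zero the time axis.

    Raises ``ValueError`` when every sample falls inside the deadband.
    """
    keep = series.t_rel >= deadband_s
    if not np.any(keep):
        raise ValueError(
            f"all samples of closure at {series.closure_time_h} h fall inside "
            f"the {deadband_s} s deadband"
        )
    return ClosureSeries(
        chamber_id=series.chamber_id,
        site=series.site,
        label_position=series.label_position,
        condition=series.condition,
        closure_time_h=series.closure_time_h,
        t_rel=series.t_rel[keep] - deadband_s,
        x12c=series.x12c[keep],
        x13c=series.x13c[keep],
        chamber_volume_m3=series.chamber_volume_m3,
        collar_area_m2=series.collar_area_m2,
        air_temperature_k=series.air_temperature_k,
        air_pressure_pa=series.air_pressure_pa,
    )


def mole_fraction_slope_to_flux(
    slope: float,
    volume_m3: float,
    area_m2: float,
    temperature_k: float,
    pressure_pa: float,
) -> float:
    """Convert a headspace mole-fraction rate to an areal flux.

    ``slope`` is in umol mol-1 s-1; the ideal-gas molar density of the
    chamber air times the headspace volume per collar area gives

        F = slope * P * V / (R * T * A)   [umol m-2 s-1]
    """
    return slope * pressure_pa * volume_m3 / (R_GAS * temperature_k * area_m2)


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS fit y = b0 + b1 t; returns (slope, intercept, r2, residual_sd)."""
    coeffs = np.polyfit(t, y, 1)
    slope, intercept = float(coeffs[0]), float(coeffs[1])
    resid = y - (intercept + slope * t)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(t) - 2, 1)
    return slope, intercept, r2, float(np.sqrt(ss_res / dof))


def fit_linear(
    series: ClosureSeries,
    window_s: float = DEFAULT_LINEAR_WINDOW_S,
    channel: str = "total",
) -> FitResult:
    """OLS slope of a mole-fraction channel over the first ``window_s`` seconds.

    ``channel`` is "total" (x12C + x13C), "x12c" or "x13c".  The series is
    assumed already deadband-trimmed.  Requires >= 3 samples in the window.
    """
    y_full = {"total": series.x_total, "x12c": series.x12c, "x13c": series.x13c}[channel]
    in_win = series.t_rel <= window_s
    t, y = series.t_rel[in_win], y_full[in_win]
    if len(t) < 3:
        raise ValueError(
            f"linear fit needs >= 3 samples within {window_s} s, got {len(t)}"
        )
    slope, _, r2, rsd = _ols_line(t, y)
    return FitResult(slope=slope, r2=r2, residual_sd=rsd, converged=True, method="linear")


def _exp_model(t: np.ndarray, c0: float, s0: float, a: float) -> np.ndarray:
    # C(t) = Cs + (C0 - Cs) e^{-a t} with Cs - C0 = s0 / a, written with
    # expm1 so the a -> 0 (pure linear) limit is numerically stable.
    return c0 - s0 * np.expm1(-a * t) / a


def fit_exponential(series: ClosureSeries, channel: str = "total") -> FitResult:
    """Nonlinear fit of the exponential closure model over the full series.

    Parameterized as (C0, s0, a) where s0 = a (Cs - C0) is the initial
    slope — the flux-defining quantity — so the near-linear regime (a -> 0)
    stays well conditioned.  Non-convergence or a <= 0 is reported as a
    failed fit; callers fall back to the linear flux.
    """
    y = {"total": series.x_total, "x12c": series.x12c, "x13c": series.x13c}[channel]
    t = series.t_rel
    if len(t) < 10:
        raise ValueError(f"exponential fit needs >= 10 samples, got {len(t)}")
    slope0, intercept0, _, _ = _ols_line(t, y)
    p0 = (intercept0, slope0 if slope0 != 0 else 1e-6, 1e-3)
    try:
        popt, _ = curve_fit(
            _exp_model,
            t,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-8], [np.inf, np.inf, 1.0]),
            maxfev=5000,
            ftol=1e-14,
            xtol=1e-14,
            gtol=1e-14,
        )
    except (RuntimeError, ValueError):
        return FitResult(
            slope=np.nan, r2=-np.inf, residual_sd=np.nan, converged=False,
            method="exponential",
        )
    c0, s0, a = (float(v) for v in popt)
    resid = y - _exp_model(t, c0, s0, a)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(t) - 3, 1)
    cs = c0 + s0 / a
    return FitResult(
        slope=s0,
        r2=r2,
        residual_sd=float(np.sqrt(ss_res / dof)),
        converged=a > 0 and np.isfinite(s0),
        method="exponential",
        params={"c0": c0, "cs": cs, "a": a},
    )


def select_flux(linear: FitResult | None, exponential: FitResult | None) -> tuple[FitResult | None, str]:
    """Choose between the linear and exponential flux for a closure.

    The exponential flux is used preferentially, but only when its fit
    converged with a positive rate and its R2 is not more than ``R2_MARGIN``
    below the linear R2; otherwise the linear flux replaces it.  Returns the
    chosen fit and a QC flag ("ok", "replaced_by_linear" or "rejected").
    """
    lin_ok = linear is not None and linear.converged and np.isfinite(linear.slope)
    exp_ok = (
        exponential is not None
        and exponential.converged
        and np.isfinite(exponential.slope)
        and exponential.params.get("a", 0.0) > 0
    )
    if exp_ok and (not lin_ok or exponential.r2 >= linear.r2 - R2_MARGIN):
        return exponential, "ok"
    if lin_ok:
        return linear, "replaced_by_linear" if exponential is not None else "ok"
    return None, "rejected"


def isotopologue_fluxes(series: ClosureSeries, window_s: float = DEFAULT_LINEAR_WINDOW_S) -> tuple[float, float]:
    """(F_12C, F_13C) from independent 120 s linear fits on each isotopologue.

    The series must already be deadband-trimmed.  Both slopes go through the
    same ideal-gas conversion, so F_total from the total-channel linear fit
    equals F_12C + F_13C by linearity of OLS.
    """
    f12 = fit_linear(series, window_s, channel="x12c")
    f13 = fit_linear(series, window_s, channel="x13c")
    conv = lambda s: mole_fraction_slope_to_flux(
        s,
        series.chamber_volume_m3,
        series.collar_area_m2,
        series.air_temperature_k,
        series.air_pressure_pa,
    )
    return conv(f12.slope), conv(f13.slope)


def delta13C_from_fluxes(f_12c: float, f_13c: float) -> float:
    """d13C (permil vs VPDB) of the efflux from its isotopologue flux ratio.

    delta = ((F13/F12) / R_VPDB - 1) * 1000.  Undefined (nan) when F12 <= 0.
    """
    if f_12c <= 0:
        return np.nan
    return ((f_13c / f_12c) / R_VPDB - 1.0) * 1000.0


def excess_13C_flux(
    f_13c: float, f_12c: float, baseline_delta13c: float
) -> tuple[float, bool]:
    """Label-derived 13C flux above the chamber's pre-injection baseline.

    The baseline d13C (mean over the chamber's pre-injection closures) fixes
    the 13C/12C ratio the unlabelled efflux would have; the excess is

        F_excess = F13 - F12 * R_VPDB * (1 + baseline/1000)

    Negative results (measurement noise) are floored at 0 and flagged.
    Returns ``(excess, floored)``.
    """
    expected = f_12c * R_VPDB * (1.0 + baseline_delta13c / 1000.0)
    excess = f_13c - expected
    if excess < 0:
        return 0.0, True
    return excess, False


# ---------------------------------------------------------------------------
# Batch processing of a closures table
# ---------------------------------------------------------------------------

def _estimate_closure(
    series: ClosureSeries,
    deadband_s: float,
    window_s: float,
) -> FluxEstimate:
    trimmed = apply_deadband(series, deadband_s)
    conv = lambda s: mole_fraction_slope_to_flux(
        s,
        trimmed.chamber_volume_m3,
        trimmed.collar_area_m2,
        trimmed.air_temperature_k,
        trimmed.air_pressure_pa,
    )
    try:
        lin = fit_linear(trimmed, window_s)
    except ValueError:
        lin = None
    try:
        expf = fit_exponential(trimmed)
    except ValueError:
        expf = None
    chosen, qc = select_flux(lin, expf)
    if chosen is None:
        return FluxEstimate(
            f_total=np.nan, f_12c=np.nan, f_13c=np.nan, delta13c=np.nan,
            excess_13c=np.nan, fit_method="none", r2=np.nan,
            residual_sd=np.nan, exp_rate=np.nan, qc_flag="rejected",
        )
    f12, f13 = isotopologue_fluxes(trimmed, window_s)
    return FluxEstimate(
        f_total=conv(chosen.slope),
        f_12c=f12,
        f_13c=f13,
        delta13c=delta13C_from_fluxes(f12, f13),
        excess_13c=np.nan,  # filled once the chamber baseline is known
        fit_method=chosen.method,
        r2=chosen.r2,
        residual_sd=chosen.residual_sd,
        exp_rate=chosen.params.get("a", np.nan),
        qc_flag=qc,
    )


def _flag_outliers(df: pd.DataFrame, value_col: str = "excess13C") -> pd.Series:
    """Deterministic surrogate for the study's visual QC of flux series.

    Within each chamber, a closure is rejected when its flux deviates from a
    5-point rolling median by more than ``OUTLIER_Z`` robust standard
    deviations (1.4826 * MAD of the rolling-median residuals).
    """
    flags = pd.Series(False, index=df.index)
    for _, grp in df.groupby("chamber_id", observed=True):
        vals = grp.sort_values("closure_time_h")[value_col]
        smooth = vals.rolling(5, center=True, min_periods=1).median()
        resid = vals - smooth
        mad = float(np.nanmedian(np.abs(resid - np.nanmedian(resid))))
        scale = 1.4826 * mad
        if scale <= 0:
            continue
        bad = resid.abs() / scale > OUTLIER_Z
        flags.loc[bad[bad].index] = True
    return flags


def closures_from_frame(df: pd.DataFrame) -> list[ClosureSeries]:
    """Build ClosureSeries objects from a long-format closures table."""
    out: list[ClosureSeries] = []
    cols = ["chamber_id", "closure_index"]
    for (_, _), grp in df.groupby(cols, sort=True, observed=True):
        grp = grp.sort_values("t_s")
        first = grp.iloc[0]
        out.append(
            ClosureSeries(
                chamber_id=str(first["chamber_id"]),
                site=str(first["site"]),
                label_position=str(first["label_position"]),
                condition=str(first["condition"]),
                closure_time_h=float(first["closure_time_h"]),
                t_rel=grp["t_s"].to_numpy(),
                x12c=grp["x12C_umol_mol"].to_numpy(),
                x13c=grp["x13C_umol_mol"].to_numpy(),
                chamber_volume_m3=float(first["chamber_volume_m3"]),
                collar_area_m2=float(first["collar_area_m2"]),
                air_temperature_k=float(first["air_temperature_K"]),
                air_pressure_pa=float(first["air_pressure_Pa"]),
            )
        )
    return out


def process_closures(
    closures: pd.DataFrame | Sequence[ClosureSeries],
    deadband_s: float = DEFAULT_DEADBAND_S,
    linear_window_s: float = DEFAULT_LINEAR_WINDOW_S,
    baseline_window_h: float = 12.0,
) -> pd.DataFrame:
    """Estimate fluxes for every closure of every chamber.

    Accepts either a long-format closures table (columns chamber_id, site,
    label_position, condition, closure_index, closure_time_h, t_s,
    x12C_umol_mol, x13C_umol_mol plus chamber geometry/conditions) or a
    sequence of :class:`ClosureSeries`.

    For each chamber, the isotopic baseline is the mean d13C over its
    pre-injection closures (closure_time_h in [-baseline_window_h, 0)); the
    excess 13C flux of every closure is computed against that baseline.
    Returns a fluxes table with one row per closure.
    """
    if isinstance(closures, pd.DataFrame):
        closures = closures_from_frame(closures)
    rows = []
    for series in closures:
        est = _estimate_closure(series, deadband_s, linear_window_s)
        rows.append(
            {
                "chamber_id": series.chamber_id,
                "site": series.site,
                "label_position": series.label_position,
                "condition": series.condition,
                "closure_time_h": series.closure_time_h,
                "F_total": est.f_total,
                "F_12C": est.f_12c,
                "F_13C": est.f_13c,
                "delta13C_permil": est.delta13c,
                "fit_method": est.fit_method,
                "r2": est.r2,
                "exp_rate_per_s": est.exp_rate,
                "qc_flag": est.qc_flag,
            }
        )
    out = pd.DataFrame(rows)

    # per-chamber pre-injection baseline d13C, then excess 13C flux
    pre = out[(out["closure_time_h"] < 0) & (out["closure_time_h"] >= -baseline_window_h)]
    baselines = pre.groupby("chamber_id", observed=True)["delta13C_permil"].mean()
    excess = np.full(len(out), np.nan)
    floored = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        base = baselines.get(row.chamber_id, np.nan)
        if np.isnan(base) or not np.isfinite(row.F_12C):
            continue
        excess[i], floored[i] = excess_13C_flux(row.F_13C, row.F_12C, base)
    out["baseline_delta13C"] = out["chamber_id"].map(baselines)
    out["excess13C"] = excess
    out["excess_floored"] = floored

    bad = _flag_outliers(out)
    out.loc[bad, "qc_flag"] = "rejected"
    out.loc[bad, "excess13C"] = np.nan
    return out
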