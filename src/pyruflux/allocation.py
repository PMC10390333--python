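"""Cumulative 13C recoveries and the biosynthesis/TCA/other/VOC partition.

The carboxyl carbon (C1) of pyruvate is released as CO2 during both
biosynthetic decarboxylation and the TCA cycle, while the carbonyl carbon
(C2) is released only in the TCA cycle.  With cumulative excess 13C-CO2
recoveries expressed as shares of the injected 13C, the partition is

    % biosynthesis = 100 (cumC1 - cumC2) / injected
    % TCA cycle    = 100  cumC2 / injected
    % other        = 100 - 100 cumC1 / injected

which sums to 100 exactly by construction.  The VOC share of biosynthesis is
the cumulative 13C emitted in enriched volatiles divided by the biosynthesis
pool (cumC1 - cumC2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chamber_flux import MASS_13C_G_MOL

__all__ = [
    "BIN_EDGES_H",
    "bin_series",
    "cumulative_13C",
    "paired_biosynthesis",
    "partition",
    "condition_change",
    "compare_conditions_lme",
    "AllocationResult",
    "scenario_allocation",
]

#: Right-closed bin edges (h) for time-binned flux series; labels are the
#: right edge of each bin.
BIN_EDGES_H = [0, 3, 6, 12, 18, 24, 30, 36, 42, 48]


def bin_series(
    flux_series: pd.DataFrame,
    value_col: str = "excess13C",
    time_col: str = "closure_time_h",
) -> pd.DataFrame:
    """Mean flux per chamber within the fixed half-open time bins (0,3], ... (42,48].

    Empty bins appear as missing values with flag ``empty``.  Returns columns
    chamber_id, bin_h, mean_flux, flag.
    """
    df = flux_series.copy()
    df["bin_h"] = pd.cut(df[time_col], bins=BIN_EDGES_H, right=True, labels=BIN_EDGES_H[1:])
    out = (
        df.groupby(["chamber_id", "bin_h"], observed=False)[value_col]
        .mean()
        .rename("mean_flux")
        .reset_index()
    )
    out["bin_h"] = out["bin_h"].astype(int)
    out["flag"] = np.where(out["mean_flux"].isna(), "empty", "ok")
    return out


def cumulative_13C(
    times_h: np.ndarray,
    flux_umol_m2_h: np.ndarray,
    collar_area_m2: float,
    t0: float = 0.0,
    t1: float = 48.0,
) -> float:
    """Trapezoidal 0-48 h integral of an excess 13C flux, as mg 13C per chamber.

    ``flux_umol_m2_h`` is in umol 13C m-2 h-1.  Missing values (rejected
    closures) are dropped, which makes the trapezoid interpolate linearly
    across them.  Requires >= 2 valid points within [t0, t1].
    """
    t = np.asarray(times_h, dtype=float)
    f = np.asarray(flux_umol_m2_h, dtype=float)
    keep = np.isfinite(f) & (t >= t0) & (t <= t1)
    t, f = t[keep], f[keep]
    if len(t) < 2:
        raise ValueError(f"need >= 2 valid flux points in [{t0}, {t1}] h, got {len(t)}")
    order = np.argsort(t)
    integral = float(np.trapezoid(f[order], t[order]))  # umol m-2
    return integral * collar_area_m2 * MASS_13C_G_MOL / 1000.0  # mg


def paired_biosynthesis(binned_c1: pd.Series, binned_c2: pd.Series) -> pd.DataFrame:
    """Per-bin total (C1 - C2) and relative (C1/(C1+C2)) biosynthesis.

    Inputs are mean fluxes indexed by bin label for the two chambers of one
    C1/C2 pair.  The ratio is undefined (nan) where C1 + C2 <= 0.
    """
    c1, c2 = binned_c1.align(binned_c2)
    total = c1 - c2
    denom = c1 + c2
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, c1 / denom, np.nan)
    return pd.DataFrame({"total_biosynthesis": total, "relative_biosynthesis": ratio},
                        index=c1.index)


def partition(
    cum_c1_mg: float,
    cum_c2_mg: float,
    cum_voc_13c_mg: float,
    injected_13c_mg: float,
) -> dict:
    """Partition of the injected 13C into biosynthesis / TCA / other pools.

    Returns percentages plus the VOC share of the biosynthesis pool.  A
    negative biosynthesis share (cumC1 < cumC2, possible under noise) is
    reported as-is with ``flags`` noting it, never clamped.
    """
    if injected_13c_mg <= 0:
        raise ValueError("injected 13C mass must be positive")
    pct_bio = 100.0 * (cum_c1_mg - cum_c2_mg) / injected_13c_mg
    pct_tca = 100.0 * cum_c2_mg / injected_13c_mg
    pct_other = 100.0 - 100.0 * cum_c1_mg / injected_13c_mg
    bio_pool = cum_c1_mg - cum_c2_mg
    pct_voc_of_bio = 100.0 * cum_voc_13c_mg / bio_pool if bio_pool > 0 else np.nan
    flags = []
    if pct_bio < 0:
        flags.append("negative_biosynthesis")
    if bio_pool <= 0:
        flags.append("voc_share_undefined")
    return {
        "pct_bio": pct_bio,
        "pct_tca": pct_tca,
        "pct_other": pct_other,
        "pct_voc_of_bio": pct_voc_of_bio,
        "injected_13c_mg": injected_13c_mg,
        "cum_c1_mg": cum_c1_mg,
        "cum_c2_mg": cum_c2_mg,
        "cum_voc_13c_mg": cum_voc_13c_mg,
        "flags": flags,
    }


def condition_change(cum_pre: np.ndarray, cum_drought: np.ndarray) -> dict:
    """Drought/pre-drought factor and percent decrease of mean cumulative flux."""
    pre = float(np.mean(np.asarray(cum_pre, dtype=float)))
    dro = float(np.mean(np.asarray(cum_drought, dtype=float)))
    if pre == 0:
        raise ValueError("pre-condition mean is zero; factor undefined")
    factor = dro / pre
    return {"factor": factor, "percent_decrease": 100.0 * (1.0 - factor)}


def compare_conditions_lme(
    values: np.ndarray,
    condition: np.ndarray,
    site: np.ndarray,
    chamber_id: np.ndarray,
) -> dict:
    """Mixed-model comparison of a response between conditions.

    Thin wrapper over statsmodels MixedLM with a fixed condition effect and
    random intercepts for site and chamber (chamber nested in site via a
    variance component).  Returns the condition effect, its standard error,
    a t statistic, approximate d.f. and p-value.  Provided for pipeline
    completeness; it is not a bespoke estimator.
    """
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "condition": np.asarray(condition),
        "site": np.asarray(site),
        "chamber": np.asarray(chamber_id),
    })
    model = smf.mixedlm(
        "value ~ C(condition)",
        data=df,
        groups="site",
        re_formula="1",
        vc_formula={"chamber": "0 + C(chamber)"},
    )
    fit = model.fit(reml=True, method="lbfgs")
    name = [n for n in fit.params.index if n.startswith("C(condition)")][0]
    effect = float(fit.params[name])
    se = float(fit.bse[name])
    tval = effect / se if se > 0 else np.nan
    n_groups = df["site"].nunique()
    dof = max(len(df) - n_groups - 1, 1)
    from scipy import stats

    p = 2.0 * stats.t.sf(abs(tval), dof) if np.isfinite(tval) else np.nan
    return {"effect": effect, "se": se, "t": tval, "df": dof, "p": p}


@dataclass
class AllocationResult:
    """Cumulative recoveries and partition for one condition."""

    condition: str
    injected_13c_mg: float
    per_chamber: pd.DataFrame  # chamber_id, label_position, cum_13c_mg
    per_voc: pd.DataFrame  # compound, chamber_id, label_position, cum_13c_mg
    cum_c1_mean_mg: float
    cum_c2_mean_mg: float
    cum_voc_13c_mg: float
    partition: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "injected_13c_mg": self.injected_13c_mg,
            "cum_c1_mean_mg": self.cum_c1_mean_mg,
            "cum_c2_mean_mg": self.cum_c2_mean_mg,
            "cum_voc_13c_mg": self.cum_voc_13c_mg,
            "partition": self.partition,
        }


def scenario_allocation(
    fluxes: pd.DataFrame,
    voc_fluxes: pd.DataFrame,
    injected_13c_mg: float,
    collar_area_m2: float,
    condition: str | None = None,
    voc_positions: tuple[str, ...] = ("C2",),
    t1_h: float = 48.0,
) -> AllocationResult:
    """Cumulate excess fluxes per chamber and compute the condition partition.

    ``fluxes`` is the chamber-flux table (excess13C in umol m-2 s-1) and
    ``voc_fluxes`` the VOC flux table (F13C_voc in nmol m-2 s-1).  Chamber
    means of the 0-48 h cumulative recoveries enter the partition; the VOC
    numerator sums, per compound, the mean cumulative 13C over chambers of
    the positions in ``voc_positions`` (default: the C2-labelled chambers,
    whose enriched volatiles are biosynthetic products).
    """
    if condition is None:
        condition = str(fluxes["condition"].iloc[0])

    rows = []
    for chamber, grp in fluxes.groupby("chamber_id", observed=True):
        ok = grp[grp["qc_flag"] != "rejected"]
        cum = cumulative_13C(
            ok["closure_time_h"].to_numpy(),
            ok["excess13C"].to_numpy() * 3600.0,  # umol m-2 s-1 -> per h
            collar_area_m2,
            t1=t1_h,
        )
        rows.append({
            "chamber_id": chamber,
            "label_position": grp["label_position"].iloc[0],
            "cum_13c_mg": cum,
        })
    per_chamber = pd.DataFrame(rows)

    voc_rows = []
    for (compound, chamber), grp in voc_fluxes.groupby(
        ["compound", "chamber_id"], observed=True
    ):
        ok = grp[grp["qc_flag"] == "ok"]
        cum = cumulative_13C(
            ok["closure_time_h"].to_numpy(),
            ok["F13C_voc"].to_numpy() * 3600.0 / 1000.0,  # nmol/s -> umol/h
            collar_area_m2,
            t1=t1_h,
        )
        voc_rows.append({
            "compound": compound,
            "chamber_id": chamber,
            "label_position": grp["label_position"].iloc[0],
            "cum_13c_mg": cum,
        })
    per_voc = pd.DataFrame(voc_rows)

    cum_c1 = float(per_chamber.loc[per_chamber["label_position"] == "C1", "cum_13c_mg"].mean())
    cum_c2 = float(per_chamber.loc[per_chamber["label_position"] == "C2", "cum_13c_mg"].mean())
    voc_sel = per_voc[per_voc["label_position"].isin(voc_positions)]
    cum_voc = float(voc_sel.groupby("compound", observed=True)["cum_13c_mg"].mean().sum())

    result = AllocationResult(
        condition=condition,
        injected_13c_mg=injected_13c_mg,
        per_chamber=per_chamber,
        per_voc=per_voc,
        cum_c1_mean_mg=cum_c1,
        cum_c2_mean_mg=cum_c2,
        cum_voc_13c_mg=cum_voc,
    )
    result.partition = partition(cum_c1, cum_c2, cum_voc, injected_13c_mg)
    return result
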