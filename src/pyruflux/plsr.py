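"""PLS regression with VIP scores, LOO-RMSECV component selection,
backward elimination and the cross-validated F-test.

Single-response PLS (NIPALS PLS1) on autoscaled predictors.  The number of
components is chosen by leave-one-out cross-validation over 0-10 components
(0 components predicts the training mean), minimizing the root mean squared
error of the held-out predictions (RMSECV, ties to fewer components).
Predictor importance is summarized by VIP scores

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a )

with unit-norm component weights w_a and SSY_a the response variance
captured by component a, so the mean squared VIP is always 1.  Backward
elimination repeatedly removes the lowest-VIP predictor (re-selecting the
component count each step) and returns the model with the highest total
training R^2.  Model significance compares the cross-validated predictive
residuals against the residuals of the null (response-mean) model with an
F-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLSRFit",
    "EliminationTrace",
    "fit_plsr",
    "loo_rmsecv",
    "vip",
    "backward_eliminate",
    "cv_f_test",
]

MAX_COMPONENTS = 10


@dataclass
class PLSRFit:
    """A fitted single-response PLS model on autoscaled predictors."""

    predictors: list[str]
    n_components: int
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, A), unit-norm columns
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    scores: np.ndarray  # (n, A)
    coef: np.ndarray  # (p,) on the autoscaled X scale
    ssy_per_component: np.ndarray  # (A,)
    r2_per_component: np.ndarray  # (A,)
    rmsecv: np.ndarray | None = None  # index a = 0..max component count
    vip: np.ndarray | None = None
    cv_p_value: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def r2_total(self) -> float:
        return float(self.r2_per_component.sum())

    def predict(self, x: np.ndarray | pd.DataFrame) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        xs = (x - self.x_mean) / self.x_std
        return self.y_mean + xs @ self.coef


def _autoscale(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Centre/unit-scale columns; zero-variance columns are flagged and
    scaled by 1 (their centred values are all zero, so they carry no
    weight in the fit)."""
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=1)
    keep = std > 0
    safe = np.where(keep, std, 1.0)
    return (x - mean) / safe, mean, safe, keep


def fit_plsr(
    x: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    n_components: int,
) -> PLSRFit:
    """NIPALS PLS1 decomposition with ``n_components`` latent components.

    Deterministic given its inputs.  Requires n >= 3 samples and
    ``n_components <= min(n - 1, p)``.
    """
    names = list(x.columns) if isinstance(x, pd.DataFrame) else [f"x{j}" for j in range(np.asarray(x).shape[1])]
    x = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if n < 3:
        raise ValueError(f"need >= 3 samples, got {n}")
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    xs, x_mean, x_std, _ = _autoscale(x)
    y_mean = float(yv.mean())
    yr = yv - y_mean
    ss_y_total = float(np.sum(yr**2))

    e, f = xs.copy(), yr.copy()
    ws, ps, qs, ts = [], [], [], []
    for _ in range(n_components):
        w = e.T @ f
        norm = np.linalg.norm(w)
        if norm == 0:  # response fully deflated; stop early
            break
        w /= norm
        t = e @ w
        tt = float(t @ t)
        if tt == 0:
            break
        p_load = e.T @ t / tt
        q = float(f @ t / tt)
        e = e - np.outer(t, p_load)
        f = f - q * t
        ws.append(w)
        ps.append(p_load)
        qs.append(q)
        ts.append(t)
    a_eff = len(ws)
    w_mat = np.column_stack(ws) if a_eff else np.zeros((p, 0))
    p_mat = np.column_stack(ps) if a_eff else np.zeros((p, 0))
    q_vec = np.array(qs)
    t_mat = np.column_stack(ts) if a_eff else np.zeros((n, 0))
    if a_eff:
        coef = w_mat @ np.linalg.solve(p_mat.T @ w_mat, q_vec)
    else:
        coef = np.zeros(p)
    ssy = np.array([q_vec[a] ** 2 * float(t_mat[:, a] @ t_mat[:, a]) for a in range(a_eff)])
    r2 = ssy / ss_y_total if ss_y_total > 0 else np.zeros(a_eff)
    return PLSRFit(
        predictors=names,
        n_components=a_eff,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        weights=w_mat,
        x_loadings=p_mat,
        y_loadings=q_vec,
        scores=t_mat,
        coef=coef,
        ssy_per_component=ssy,
        r2_per_component=r2,
    )


def loo_rmsecv(
    x: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    max_components: int = MAX_COMPONENTS,
) -> tuple[np.ndarray, int]:
    """Leave-one-out RMSECV over 0..max_components; returns (curve, argmin).

    Component 0 predicts the training mean of the remaining samples.  Ties
    in the minimum go to fewer components.  Scaling is re-estimated inside
    every leave-one-out split.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = xv.shape
    a_max = min(max_components, n - 2, p)
    press = np.zeros(a_max + 1)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xt, yt = xv[mask], yv[mask]
        press[0] += (yv[i] - yt.mean()) ** 2
        fit = fit_plsr(xt, yt, a_max) if a_max >= 1 else None
        if fit is None:
            continue
        # predictions for every component count from one decomposition
        xs_i = (xv[i] - fit.x_mean) / fit.x_std
        r_mat = fit.weights @ np.linalg.inv(fit.x_loadings.T @ fit.weights) if fit.n_components else None
        for a in range(1, a_max + 1):
            a_use = min(a, fit.n_components)
            if a_use == 0:
                pred = fit.y_mean
            else:
                coef_a = r_mat[:, :a_use] @ fit.y_loadings[:a_use]
                pred = fit.y_mean + xs_i @ coef_a
            press[a] += (yv[i] - pred) ** 2
    rmsecv = np.sqrt(press / n)
    return rmsecv, int(np.argmin(rmsecv))


def vip(fit: PLSRFit) -> np.ndarray:
    """VIP score per predictor; the mean squared VIP equals 1 by construction."""
    p = len(fit.predictors)
    if fit.n_components == 0 or fit.ssy_per_component.sum() == 0:
        return np.ones(p)
    w2 = fit.weights**2  # columns already unit-norm
    num = w2 @ fit.ssy_per_component
    return np.sqrt(p * num / fit.ssy_per_component.sum())


@dataclass
class EliminationTrace:
    """Backward-elimination history: one entry per fitted model."""

    steps: list[dict] = field(default_factory=list)  # predictors, removed, n_components, r2
    selected_index: int = 0


def _fit_with_cv(x: pd.DataFrame, y: np.ndarray, max_components: int) -> PLSRFit:
    rmsecv, a_sel = loo_rmsecv(x, y, max_components)
    if a_sel == 0:
        # degenerate null-model selection: keep one component for the fit
        # but record that CV favoured the mean model
        fit = fit_plsr(x, y, 1)
        fit.meta["cv_selected_zero"] = True
    else:
        fit = fit_plsr(x, y, a_sel)
    fit.rmsecv = rmsecv
    fit.vip = vip(fit)
    return fit


def backward_eliminate(
    x: pd.DataFrame,
    y: pd.Series | np.ndarray,
    max_components: int = MAX_COMPONENTS,
    reselect_components: bool = True,
) -> tuple[PLSRFit, EliminationTrace]:
    """Remove the lowest-VIP predictor until one remains; keep the best model.

    At every step the component count is re-selected by LOO-RMSECV (or held
    at the first selection when ``reselect_components`` is False), the total
    training R^2 recorded, and the lowest-VIP predictor dropped.  The
    returned model maximizes recorded R^2; ties go to fewer predictors.
    """
    if not isinstance(x, pd.DataFrame):
        x = pd.DataFrame(np.asarray(x, dtype=float))
    yv = np.asarray(y, dtype=float).ravel()
    trace = EliminationTrace()
    fits: list[PLSRFit] = []
    current = x.copy()
    fixed_a: int | None = None
    while True:
        if reselect_components or fixed_a is None:
            fit = _fit_with_cv(current, yv, max_components)
            if fixed_a is None:
                fixed_a = fit.n_components
        else:
            a = min(fixed_a, current.shape[1], len(yv) - 1)
            fit = fit_plsr(current, yv, a)
            fit.vip = vip(fit)
        fits.append(fit)
        order = np.argsort(fit.vip)
        lowest = fit.predictors[int(order[0])]
        trace.steps.append({
            "predictors": list(current.columns),
            "n_components": fit.n_components,
            "r2": fit.r2_total,
            "removed": lowest if current.shape[1] > 1 else None,
        })
        if current.shape[1] == 1:
            break
        current = current.drop(columns=[lowest])
    r2s = [s["r2"] for s in trace.steps]
    # max R2; ties resolved toward fewer predictors (later steps)
    best = max(range(len(r2s)), key=lambda i: (r2s[i], i))
    trace.selected_index = best
    return fits[best], trace


def cv_f_test(
    x: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    n_components: int,
    max_components: int = MAX_COMPONENTS,
) -> dict:
    """F-test of cross-validated predictive residuals against the null model.

    F = (SS_null / df_null) / (SS_cv / df_model) with SS_null the squared
    residuals around the response mean, SS_cv the squared leave-one-out
    predictive residuals of the ``n_components``-component model,
    df_null = n - 1 and df_model = n - 1 - n_components; the p-value is the
    right tail of F(df_null, df_model).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n = len(yv)
    ss_null = float(np.sum((yv - yv.mean()) ** 2))
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xt, yt = xv[mask], yv[mask]
        if n_components == 0:
            pred = yt.mean()
        else:
            a = min(n_components, len(yt) - 1, xv.shape[1])
            fit = fit_plsr(xt, yt, a)
            pred = float(fit.predict(xv[i][None, :])[0])
        press += (yv[i] - pred) ** 2
    df_null = n - 1
    df_model = n - 1 - n_components
    if df_model <= 0:
        raise ValueError("too many components for the sample size")
    f_stat = (ss_null / df_null) / (press / df_model)
    p = float(stats.f.sf(f_stat, df_null, df_model))
    return {
        "F": f_stat,
        "p": p,
        "df_null": df_null,
        "df_model": df_model,
        "ss_null": ss_null,
        "ss_cv": press,
        "df_convention": "df_null = n - 1; df_model = n - 1 - n_components",
    }
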