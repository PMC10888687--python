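"""Factorial mixed-effects models for the storage study.

Each response is modelled as ``y ~ Day + Boar + Day:Boar`` (sum-to-zero
coded fixed effects) with a random intercept for the ejaculate nested in
boar — the dose is the repeated unit, measured fresh and after storage.
Fits use REML.  Fixed terms are tested with Wald F statistics whose
denominator degrees of freedom follow the containment rule: terms varying
within the ejaculate unit (Day, Day x Boar) use the within-unit residual
df, ``n - rank([X Z])``; the between-unit term (Boar) uses
``#units - #boars``.  Under a balanced design this reproduces the classical
split-plot ANOVA exactly, so the Day test is exactly calibrated there.

Estimated day means are marginal means (predictions averaged over boars),
which equal the raw day means under balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats

__all__ = ["ModelFit", "fit_factorial_mixed_models"]


@dataclass
class ModelFit:
    """Per-variable day means +/- SEM and fixed-term p-values."""

    variable: str
    mean_by_day: dict[str, float]
    sem_by_day: dict[str, float]
    p_day: float
    p_boar: float
    p_interaction: float
    random_effect_sd: float
    residual_sd: float
    fallback_ols: bool = False


def _term_indices(exog_names: list[str]) -> dict[str, list[int]]:
    idx = {"day": [], "boar": [], "interaction": []}
    for i, name in enumerate(exog_names):
        if name == "Intercept":
            continue
        has_day = "C(day" in name
        has_boar = "C(boar" in name
        if has_day and has_boar:
            idx["interaction"].append(i)
        elif has_day:
            idx["day"].append(i)
        elif has_boar:
            idx["boar"].append(i)
    return idx


def _wald_f(
    params: np.ndarray,
    cov: np.ndarray,
    indices: list[int],
    df_denom: float,
) -> float:
    """P-value of H0: the selected coefficients are all zero."""
    if not indices or df_denom <= 0:
        return float("nan")
    b = params[indices]
    v = cov[np.ix_(indices, indices)]
    q = len(indices)
    stat = float(b @ np.linalg.solve(v, b)) / q
    return float(stats.f.sf(stat, q, df_denom))


def _containment_dfs(
    exog: np.ndarray, groups: pd.Series, n_boars: int
) -> tuple[float, float]:
    """(within-unit df, between-unit df) for the containment rule."""
    n = exog.shape[0]
    z = pd.get_dummies(groups).to_numpy(dtype=float)
    rank_xz = np.linalg.matrix_rank(np.hstack([exog, z]))
    df_within = max(n - rank_xz, 1)
    df_between = max(z.shape[1] - n_boars, 1)
    return float(df_within), float(df_between)


def _day_marginal_means(
    params: np.ndarray,
    cov: np.ndarray,
    design_info,
    data: pd.DataFrame,
    days: list[str],
) -> tuple[dict[str, float], dict[str, float]]:
    boars = sorted(data["boar"].unique())
    means, sems = {}, {}
    for day in days:
        grid = pd.DataFrame({"day": day, "boar": boars})
        m = np.asarray(patsy.dmatrix(design_info, grid, return_type="matrix"))
        l_vec = m.mean(axis=0)
        means[day] = float(l_vec @ params)
        with np.errstate(invalid="ignore"):
            var = float(l_vec @ cov @ l_vec)
        sems[day] = float(np.sqrt(var)) if var >= 0 else float("nan")
    return means, sems


def fit_factorial_mixed_models(
    table: pd.DataFrame,
    variables: list[str],
    day_col: str = "day",
    boar_col: str = "boar",
    ejaculate_col: str = "ejaculate",
) -> pd.DataFrame:
    """Fit the factorial mixed model to each variable.

    Returns one row per variable: estimated day means and SEMs (columns
    ``mean_<day>`` / ``sem_<day>``), ``p_day``, ``p_boar``,
    ``p_interaction``, variance components and a ``fallback_ols`` flag set
    when the mixed fit failed or was singular and a fixed-effects model was
    used instead.
    """
    data = table.copy()
    data = data.rename(
        columns={day_col: "day", boar_col: "boar", ejaculate_col: "ejaculate"}
    )
    if data["boar"].nunique() < 2 or data["day"].nunique() < 2:
        raise ValueError("need at least 2 boars and 2 days")
    data["_unit"] = (
        data["boar"].astype(str) + ":" + data["ejaculate"].astype(str)
    )
    days = sorted(data["day"].unique())
    n_boars = data["boar"].nunique()

    rows = []
    for var in variables:
        sub = data.loc[~data[var].isna()].copy()
        formula = f"Q('{var}') ~ C(day, Sum) * C(boar, Sum)"
        fit_rec = _fit_one(sub, formula, var, days, n_boars)
        row = {
            "variable": var,
            **{f"mean_{d}": fit_rec.mean_by_day[d] for d in days},
            **{f"sem_{d}": fit_rec.sem_by_day[d] for d in days},
            "p_day": fit_rec.p_day,
            "p_boar": fit_rec.p_boar,
            "p_interaction": fit_rec.p_interaction,
            "random_effect_sd": fit_rec.random_effect_sd,
            "residual_sd": fit_rec.residual_sd,
            "fallback_ols": fit_rec.fallback_ols,
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def _fit_one(
    data: pd.DataFrame, formula: str, var: str, days: list[str], n_boars: int
) -> ModelFit:
    fallback = False
    result = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups=data["_unit"])
            result = model.fit(reml=True)
        if not result.converged or not np.isfinite(result.params).all():
            fallback = True
    except (np.linalg.LinAlgError, ValueError):
        fallback = True

    if fallback or result is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.ols(formula, data)
            result = model.fit()
            fallback = True
            exog = model.exog
            exog_names = model.exog_names
            params = np.asarray(result.params)
            cov = np.asarray(result.cov_params())
            df_resid = float(result.df_resid)
            df_within = df_between = df_resid
            re_sd = float("nan")
            resid_sd = float(np.sqrt(result.mse_resid))
    else:
        exog = model.exog
        exog_names = model.exog_names
        params = np.asarray(result.fe_params)
        cov = np.asarray(result.cov_params())[: len(params), : len(params)]
        df_within, df_between = _containment_dfs(
            exog, data["_unit"], n_boars
        )
        re_sd = float(np.sqrt(result.cov_re.iloc[0, 0]))
        resid_sd = float(np.sqrt(result.scale))

    idx = _term_indices(list(exog_names))
    p_day = _wald_f(params, cov, idx["day"], df_within)
    p_boar = _wald_f(params, cov, idx["boar"], df_between)
    p_int = _wald_f(params, cov, idx["interaction"], df_within)

    design_info = model.data.design_info
    means, sems = _day_marginal_means(params, cov, design_info, data, days)
    return ModelFit(
        variable=var,
        mean_by_day=means,
        sem_by_day=sems,
        p_day=p_day,
        p_boar=p_boar,
        p_interaction=p_int,
        random_effect_sd=re_sd,
        residual_sd=resid_sd,
        fallback_ols=fallback,
    )
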