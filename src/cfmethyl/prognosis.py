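"""Methylation score and survival analysis.

The methylation score of a cfDNA sample is the mean beta-value over the
detection feature windows — a tumor-burden surrogate. It is dichotomized
at the cohort median for Kaplan-Meier / log-rank analysis, and enters Cox
proportional-hazards models (continuous or dichotomized) alongside age,
sex and clinical stage; score-augmented models are compared with the base
clinical model by AIC, BIC and concordance index, with Schoenfeld-style
proportional-hazards diagnostics per covariate.

Missing beta-values are excluded from the score average (not zero-filled):
zero-filling would deflate scores for shallow samples and masquerade as
low tumor burden.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, proportional_hazard_test


def methylation_score(beta_column: pd.Series, feature_windows) -> float:
    """Mean beta over the detection windows, missing values excluded.

    Returns NaN (with a warning) when every feature window is missing.
    """
    vals = beta_column.loc[list(feature_windows)].to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    if not ok.any():
        warnings.warn("methylation score undefined: all feature windows missing")
        return float("nan")
    return float(vals[ok].mean())


def methylation_scores(beta: pd.DataFrame, feature_windows) -> pd.Series:
    """Per-sample methylation scores for a beta matrix."""
    return pd.Series({s: methylation_score(beta[s], feature_windows)
                      for s in beta.columns}, name="methylation_score")


def dichotomize_median(scores: pd.Series) -> pd.Series:
    """Split scores into 'low' (<= median) and 'high' (> median) groups.

    Ties at the median go to the low group, so 'high' means strictly above
    the cohort median and the high group is never the larger one.
    """
    if len(scores) < 2:
        raise ValueError("dichotomization needs at least 2 samples")
    med = float(np.median(scores.to_numpy(dtype=float)))
    return pd.Series(np.where(scores.to_numpy(dtype=float) > med, "high", "low"),
                     index=scores.index, name="score_group")


def km_logrank(
    survival: pd.DataFrame,
    group_col: str = "score_group",
    time_col: str = "os_months",
    event_col: str = "os_event",
) -> dict:
    """Kaplan-Meier curves, per-group median OS and a two-sided log-rank p.

    Median survival is NaN when a group's curve never crosses 0.5.
    """
    groups = survival[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"log-rank comparison needs exactly 2 groups, got {len(groups)}")
    curves, medians = {}, {}
    for g in groups:
        sub = survival[survival[group_col] == g]
        if sub.empty:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(g))
        curves[g] = kmf.survival_function_
        medians[g] = float(kmf.median_survival_time_)
    a = survival[survival[group_col] == groups[0]]
    b = survival[survival[group_col] == groups[1]]
    res = logrank_test(a[time_col], b[time_col], a[event_col], b[event_col])
    return {
        "curves": curves,
        "median_os": medians,
        "logrank_p": float(res.p_value),
        "logrank_statistic": float(res.test_statistic),
    }


def _encode(survival: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    out = pd.DataFrame(index=survival.index)
    for c in covariates:
        col = survival[c]
        if c == "sex":
            out["sex_male"] = (col == "M").astype(float)
        elif c == "stage":
            out["stage_es"] = (col == "ES").astype(float)
        elif c == "score_group":
            out["score_high"] = (col == "high").astype(float)
        else:
            out[c] = col.astype(float)
    return out


def _fit_cox(df: pd.DataFrame, time_col: str, event_col: str) -> dict:
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=time_col, event_col=event_col)
    except Exception as err:  # noqa: BLE001 - convergence failures reported, not raised
        return {"converged": False, "error": str(err)}
    summary = cph.summary
    n_events = int(df[event_col].sum())
    k = len(cph.params_)
    ph_p = {}
    try:
        ph = proportional_hazard_test(cph, df, time_transform="rank")
        ph_p = {str(i): float(p) for i, p in ph.summary["p"].items()}
    except Exception:  # diagnostics are best-effort
        pass
    return {
        "converged": True,
        "hr": summary["exp(coef)"].to_dict(),
        "ci_low": summary["exp(coef) lower 95%"].to_dict(),
        "ci_high": summary["exp(coef) upper 95%"].to_dict(),
        "coef": summary["coef"].to_dict(),
        "coef_se": summary["se(coef)"].to_dict(),
        "p": summary["p"].to_dict(),
        "aic": float(cph.AIC_partial_),
        "bic": float(-2 * cph.log_likelihood_ + k * np.log(max(n_events, 1))),
        "concordance": float(cph.concordance_index_),
        "ph_test_p": ph_p,
        "n_events": n_events,
    }


def cox_models(
    survival: pd.DataFrame,
    score_col: str = "methylation_score",
    time_col: str = "os_months",
    event_col: str = "os_event",
    adjust_for: tuple = ("age", "sex", "stage"),
) -> dict:
    """Univariable and multivariable Cox models with model comparison.

    Fits univariable models for the continuous score, the dichotomized
    score and each clinical covariate; a base multivariable model with the
    clinical covariates only; and score-augmented multivariable models.
    AIC/BIC/concordance allow comparing base vs augmented fits. Stage is
    encoded as a binary limited/extensive indicator and sex as a male
    indicator. A warning (not an error) fires when events are scarce
    relative to the number of covariates.
    """
    df = survival.dropna(subset=[time_col, event_col, score_col]).copy()
    if "score_group" not in df.columns:
        df["score_group"] = dichotomize_median(df[score_col])
    n_events = int(df[event_col].sum())
    if n_events < 5 * (len(adjust_for) + 1):
        warnings.warn(f"only {n_events} events for {len(adjust_for) + 1} covariates; "
                      "multivariable estimates may be unstable")
    base_time = df[[time_col, event_col]].astype(float)

    def model(covs):
        enc = _encode(df, list(covs))
        return _fit_cox(pd.concat([enc, base_time], axis=1), time_col, event_col)

    results = {
        "uni_score_continuous": model([score_col]),
        "uni_score_dichotomized": model(["score_group"]),
        "multi_base": model(list(adjust_for)),
        "multi_score_continuous": model([score_col, *adjust_for]),
        "multi_score_dichotomized": model(["score_group", *adjust_for]),
    }
    for c in adjust_for:
        results[f"uni_{c}"] = model([c])
    comparison = {
        name: {k: res.get(k) for k in ("aic", "bic", "concordance")}
        for name, res in results.items()
        if name.startswith("multi_") and res.get("converged")
    }
    results["comparison"] = comparison
    return results
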