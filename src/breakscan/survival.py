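"""Survival validation of the breakpoint classifier.

Kaplan-Meier curves, two-group log-rank tests, and univariate /
multivariate Cox proportional-hazards fits for the two study endpoints:
disease-free interval (loco-regional, contralateral or metastatic relapse)
and metastasis-free interval (metastasis only).  Fits delegate to
lifelines; event-time ties use the Efron approximation (lifelines'
default).  Hazard ratios are reported as relative risks with Wald 95%
confidence intervals and Wald p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

#: Covariates of the reference multivariate model (grade II/III vs I, KI67
#: class, genomic grade, breakpoint class).
MULTIVARIATE_SET = ("grade23", "ki67_high", "gg3", "high_breakpoints")


@dataclass(frozen=True)
class SurvivalFit:
    """One covariate's proportional-hazards summary."""

    variable: str
    relative_risk: float
    ci95: tuple
    p: float
    test: str = "wald"
    coef: float = 0.0
    se: float = 0.0

    def __post_init__(self):
        if not self.ci95[0] <= self.relative_risk <= self.ci95[1]:
            raise ValueError("CI does not bracket the relative risk")


def _check_times_events(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.ndim != 1 or times.shape != events.shape:
        raise ValueError("times and events must be 1-D and equally long")
    if np.any(times <= 0) or np.any(~np.isfinite(times)):
        raise ValueError("times must be positive and finite")
    if set(np.unique(events.astype(float))) - {0.0, 1.0}:
        raise ValueError("events must be binary")
    return times, events.astype(int)


def km_curve(times, events, group=None) -> dict:
    """Product-limit survival estimate, per group if ``group`` is given.

    Returns a dict mapping group label (or ``"all"``) to a DataFrame with
    columns ``time`` and ``survival``; the curve starts at S(0) = 1 and is
    non-increasing.
    """
    times, events = _check_times_events(times, events)
    group = np.asarray(["all"] * len(times)) if group is None else np.asarray(group)
    curves = {}
    for g in pd.unique(group):
        mask = group == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
        )
    return curves


def logrank_test(times, events, group) -> tuple:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    times, events = _check_times_events(times, events)
    group = np.asarray(group)
    labels = pd.unique(group)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly two groups, got {len(labels)}")
    mask = group == labels[0]
    res = _ll_logrank(times[mask], times[~mask], events[mask], events[~mask])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    df: pd.DataFrame,
    covariates,
    time_col: str,
    event_col: str,
    multivariate: bool = False,
) -> list:
    """Cox proportional-hazards fit(s) of one endpoint.

    Univariate mode fits each covariate alone; multivariate fits them
    jointly.  Rows with missing values in the used columns are dropped per
    fit.  Constant or collinear covariates and non-convergence raise with
    an explicit message rather than returning silent garbage.
    """
    covariates = list(covariates)
    fits: list = []
    groups = [[c] for c in covariates] if not multivariate else [covariates]
    for cols in groups:
        sub = df[cols + [time_col, event_col]].dropna()
        _check_times_events(sub[time_col], sub[event_col])
        x = sub[cols].to_numpy(float)
        if any(np.ptp(x[:, i]) == 0 for i in range(x.shape[1])):
            raise ValueError(f"constant covariate among {cols}")
        design = np.column_stack([np.ones(len(x)), x])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(f"collinear covariates: {cols}")
        if int(sub[event_col].sum()) <= len(cols):
            raise ValueError(
                f"{int(sub[event_col].sum())} events cannot support {len(cols)} covariate(s)"
            )
        cph = CoxPHFitter()
        try:
            cph.fit(sub, duration_col=time_col, event_col=event_col)
        except ConvergenceError as exc:
            raise RuntimeError(f"Cox fit did not converge for {cols}: {exc}") from exc
        summ = cph.summary
        for c in cols:
            fits.append(
                SurvivalFit(
                    variable=c,
                    relative_risk=float(summ.loc[c, "exp(coef)"]),
                    ci95=(
                        float(summ.loc[c, "exp(coef) lower 95%"]),
                        float(summ.loc[c, "exp(coef) upper 95%"]),
                    ),
                    p=float(summ.loc[c, "p"]),
                    test="wald",
                    coef=float(summ.loc[c, "coef"]),
                    se=float(summ.loc[c, "se(coef)"]),
                )
            )
    return fits


def prepare_survival_covariates(cohort: pd.DataFrame, threshold: int = 34) -> pd.DataFrame:
    """Derive the binary covariates of the reference multivariate model.

    Adds ``grade23`` (grade II/III vs I), ``ki67_high`` (>= 14%), ``gg3``
    (standardized GGI > 0) and ``high_breakpoints`` (count > threshold) to
    a validated cohort table; missing inputs propagate as NaN.
    """
    out = cohort.copy()
    out["grade23"] = np.where(
        cohort["grade"].isna(), np.nan, (cohort["grade"] >= 2).astype(float)
    )
    out["ki67_high"] = np.where(
        cohort["ki67_fraction"].isna(),
        np.nan,
        (cohort["ki67_fraction"] >= 0.14).astype(float),
    )
    out["gg3"] = np.where(cohort["ggi"].isna(), np.nan, (cohort["ggi"] > 0).astype(float))
    out["high_breakpoints"] = (cohort["breakpoint_count"] > threshold).astype(float)
    return out
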