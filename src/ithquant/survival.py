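"""Survival and association machinery: Kaplan-Meier, log-rank, Cox
proportional hazards, a time-dependent-covariate PH check, and categorical
association tables.

Cohorts are plain pandas DataFrames with columns ``patient_id``,
``time_months`` (> 0), ``event`` (0/1) and optional covariates; two
endpoints are supported by convention — the breast-cancer-specific-survival
style primary endpoint in (``time_months``, ``event``) and a distant
metastasis style endpoint in (``dmfs_time_months``, ``dmfs_event``).

Cox model fitting and Kaplan-Meier estimation delegate to lifelines (Efron
tie handling, Newton convergence, Wald inference).  The two-group log-rank
test is implemented directly over pooled risk sets in numpy so that the
minimum-p cut-point scan can evaluate thousands of candidate splits cheaply;
it agrees with lifelines' implementation (verified in the test suite).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.utils import to_episodic_format
from scipy import stats

__all__ = [
    "CoxFit",
    "KMCurve",
    "validate_cohort",
    "endpoint_columns",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "ph_check",
    "association_table",
    "anova_across",
]

_ENDPOINTS = {
    "bcss": ("time_months", "event"),
    "dmfs": ("dmfs_time_months", "dmfs_event"),
}


def endpoint_columns(endpoint: str = "bcss") -> tuple[str, str]:
    """(time column, event column) for a named endpoint."""
    try:
        return _ENDPOINTS[endpoint]
    except KeyError:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of "
                         f"{sorted(_ENDPOINTS)}") from None


def validate_cohort(cohort: pd.DataFrame, endpoint: str = "bcss") -> pd.DataFrame:
    """Check cohort invariants: positive times, binary events, unique ids."""
    tcol, ecol = endpoint_columns(endpoint)
    for col in ("patient_id", tcol, ecol):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks column {col!r}")
    if cohort["patient_id"].duplicated().any():
        raise ValueError("duplicate patient ids in cohort")
    if (cohort[tcol] <= 0).any():
        raise ValueError("survival times must be positive")
    if not cohort[ecol].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return cohort


@dataclasses.dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    label: str | None = None

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclasses.dataclass
class CoxFit:
    """Cox proportional-hazards fit summary."""

    params: pd.Series  # betas
    bse: pd.Series
    pvalues: pd.Series
    hazard_ratios: pd.Series
    conf_int: pd.DataFrame  # exp scale, 95%
    log_likelihood: float
    n: int
    n_events: int
    penalty: float = 0.0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.params,
            "se(coef)": self.bse,
            "HR": self.hazard_ratios,
            "HR 95% lower": self.conf_int.iloc[:, 0],
            "HR 95% upper": self.conf_int.iloc[:, 1],
            "p": self.pvalues,
        })


def km_estimate(cohort: pd.DataFrame, group: pd.Series | np.ndarray | None = None,
                endpoint: str = "bcss") -> dict[str, KMCurve] | KMCurve:
    """Kaplan-Meier curves, optionally per group.

    Returns a single :class:`KMCurve` when ``group`` is None, else a dict
    keyed by group label.  Empty groups raise.
    """
    tcol, ecol = endpoint_columns(endpoint)
    if len(cohort) == 0:
        raise ValueError("empty cohort")

    def one(sub: pd.DataFrame, label: str | None) -> KMCurve:
        if len(sub) == 0:
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[tcol], sub[ecol])
        tl = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
        cens = np.sort(sub.loc[sub[ecol] == 0, tcol].to_numpy(dtype=float))
        return KMCurve(times=tl, survival=surv, at_risk=at_risk,
                       censor_times=cens, label=label)

    if group is None:
        return one(cohort, None)
    group = np.asarray(group)
    return {str(g): one(cohort[group == g], str(g)) for g in pd.unique(group)}


def logrank_test(time: np.ndarray, event: np.ndarray,
                 labels: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank test with pooled-risk-set tie handling.

    Returns (chi-square statistic with 1 df, p-value).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if groups.size != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {groups.size}")
    if event.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    in1 = labels == groups[0]

    order = np.argsort(time, kind="stable")
    t, e, g1 = time[order], event[order], in1[order].astype(float)

    # distinct event times; risk sets by reverse cumulative counts
    uniq, first = np.unique(t, return_index=True)
    n_total = len(t)
    # at-risk counts just before each distinct time
    n_at = n_total - first
    n1_at = g1[::-1].cumsum()[::-1][first]
    # events at each distinct time
    d_tot = np.add.reduceat(e, first)
    d1 = np.add.reduceat(e * g1, first)
    has_event = d_tot > 0

    nj = n_at[has_event].astype(float)
    n1j = n1_at[has_event]
    dj = d_tot[has_event].astype(float)
    d1j = d1[has_event]

    exp1 = dj * n1j / nj
    with np.errstate(invalid="ignore", divide="ignore"):
        var = dj * (n1j / nj) * (1.0 - n1j / nj) * (nj - dj) / (nj - 1.0)
    var = np.where(nj > 1, var, 0.0)
    V = var.sum()
    if V <= 0:
        return 0.0, 1.0
    stat = float((d1j - exp1).sum() ** 2 / V)
    return stat, float(stats.chi2.sf(stat, df=1))


def cox_fit(cohort: pd.DataFrame, covariates: list[str], penalty: float = 0.0,
            endpoint: str = "bcss") -> CoxFit:
    """Multivariable Cox PH fit (Efron ties) with Wald inference."""
    tcol, ecol = endpoint_columns(endpoint)
    if cohort[ecol].sum() == 0:
        raise ValueError("Cox fit needs at least one event")
    df = cohort[[tcol, ecol, *covariates]].dropna()
    cph = CoxPHFitter(penalizer=penalty)
    cph.fit(df, duration_col=tcol, event_col=ecol)
    ci = np.exp(cph.confidence_intervals_)
    return CoxFit(
        params=cph.params_.copy(),
        bse=cph.standard_errors_.copy(),
        pvalues=cph.summary["p"].copy(),
        hazard_ratios=np.exp(cph.params_),
        conf_int=ci,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(df[ecol].sum()),
        penalty=penalty,
    )


def ph_check(cohort: pd.DataFrame, covariate: str,
             endpoint: str = "bcss", time_transform: str = "log",
             ) -> tuple[float, float]:
    """Proportional-hazards check via a time-dependent covariate.

    Augments the single-covariate Cox model with an interaction term
    ``covariate * f(t)`` (``f`` = log by default, identity optionally) fitted
    as a genuine time-varying covariate over episode-split data, and returns
    (interaction beta, Wald p).  PH is conventionally "satisfied" when
    p >= 0.05.
    """
    tcol, ecol = endpoint_columns(endpoint)
    x = cohort[covariate].to_numpy(dtype=float)
    if np.nanstd(x) == 0:
        raise ValueError(f"covariate {covariate!r} is constant (degenerate design)")
    df = cohort[["patient_id", tcol, ecol, covariate]].dropna().copy()
    long = to_episodic_format(df, duration_col=tcol, event_col=ecol,
                              id_col="patient_id")
    if time_transform == "log":
        ft = np.log(long["stop"].to_numpy(dtype=float))
    elif time_transform == "identity":
        ft = long["stop"].to_numpy(dtype=float)
    else:
        raise ValueError("time_transform must be 'log' or 'identity'")
    inter = f"{covariate}_x_{time_transform}t"
    long[inter] = long[covariate].to_numpy(dtype=float) * ft
    ctv = CoxTimeVaryingFitter()
    ctv.fit(long[["patient_id", "start", "stop", ecol, covariate, inter]],
            id_col="patient_id", start_col="start", stop_col="stop",
            event_col=ecol)
    return float(ctv.params_[inter]), float(ctv.summary.loc[inter, "p"])


def association_table(groups, categorical) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) between two labellings."""
    table = pd.crosstab(pd.Series(groups), pd.Series(categorical))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("association table needs >= 2 levels on both margins")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins in association table")
    stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(stat), float(p)


def anova_across(groups, values) -> tuple[float, float]:
    """One-way ANOVA of a continuous variable across groups."""
    groups = np.asarray(groups)
    values = np.asarray(values, dtype=float)
    keep = ~np.isnan(values)
    groups, values = groups[keep], values[keep]
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)
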