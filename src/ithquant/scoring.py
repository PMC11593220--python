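"""Heterogeneity scoring: feature normalization, family scores, univariate
screening, the Cox-beta-weighted overall ITH score, and optimal-cut-point
dichotomization.

The overall intra-tumor heterogeneity (ITH) score is a linear risk score

    score_i = a + sum_k b_k * x_ik

where the x_ik are cohort-wise min-max scaled (0-100) heterogeneity
features that passed univariate Cox screening against outcome, the b_k are
the coefficients of a multivariable Cox proportional-hazards fit over the
screened features, and a is a constant offset (0 by default — a Cox partial
likelihood carries no intercept, so a only shifts the scale).  The score is
dichotomized at the cut-point minimizing the two-group log-rank p-value over
all candidate splits that leave at least a minimum fraction of patients in
each group; because that minimum-p selection is optimistic, a
Miller-Siegmund-corrected p-value is reported alongside the raw one.

The public surface follows the Model/Results convention:
:class:`ITHScoreModel` holds the data, ``fit()`` returns an
:class:`ITHScoreResults` with estimates, diagnostics and a ``summary()``.
The individual pipeline stages are exposed as functions for direct use.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from . import survival as surv
from .catalogue import FeatureCatalogue, default_catalogue

logger = logging.getLogger(__name__)

__all__ = [
    "scale_features",
    "family_score",
    "screen_features",
    "prune_collinear",
    "optimal_cutpoint",
    "dichotomize",
    "CutpointResult",
    "ITHScoreModel",
    "ITHScoreResults",
]


def scale_features(fm: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Min-max scale every feature to [0, 100] across the cohort.

    Constant and all-missing features cannot be scaled; they are dropped with
    a warning.  Returns ``(scaled, bounds)`` where ``bounds`` holds the
    per-feature min/max used (needed to score new patients on the same scale).
    """
    lo = fm.min(axis=0, skipna=True)
    hi = fm.max(axis=0, skipna=True)
    keep = (hi - lo) > 0
    dropped = fm.columns[~keep.fillna(False)].tolist()
    if dropped:
        logger.warning("scale_features: dropping %d constant/empty features: %s%s",
                       len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
    cols = fm.columns[keep.fillna(False)]
    scaled = (fm[cols] - lo[cols]) / (hi[cols] - lo[cols]) * 100.0
    bounds = pd.DataFrame({"min": lo[cols], "max": hi[cols]})
    return scaled, bounds


def family_score(fm_scaled: pd.DataFrame, catalogue: FeatureCatalogue,
                 family: str) -> pd.Series:
    """Per-patient family heterogeneity score: mean of the scaled member
    features, pairwise-complete.  Patients with no non-missing member feature
    get a missing score."""
    members = [n for n in catalogue.family_members(family) if n in fm_scaled.columns]
    if not members:
        raise ValueError(f"no features of family {family!r} present")
    return fm_scaled[members].mean(axis=1, skipna=True).rename(f"{family}_score")


def screen_features(fm_scaled: pd.DataFrame, cohort: pd.DataFrame,
                    alpha: float = 0.05, endpoint: str = "bcss") -> pd.DataFrame:
    """Univariate Cox screening of each feature against outcome.

    Returns a DataFrame indexed by feature with columns ``beta``, ``se``,
    ``p`` and ``retained`` (Wald p < alpha).  Features whose univariate fit
    fails to converge are excluded (retained=False, p=NaN) and logged.
    """
    tcol, ecol = surv.endpoint_columns(endpoint)
    if cohort[ecol].sum() == 0:
        raise ValueError("screening needs at least one event")
    base = cohort.set_index("patient_id")[[tcol, ecol]]
    rows = {}
    for name in fm_scaled.columns:
        df = base.join(fm_scaled[name]).dropna()
        if df[name].nunique() < 2 or df[ecol].sum() == 0:
            rows[name] = (np.nan, np.nan, np.nan, False)
            continue
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col=tcol, event_col=ecol)
            beta = float(cph.params_.iloc[0])
            se = float(cph.standard_errors_.iloc[0])
            p = float(cph.summary["p"].iloc[0])
            rows[name] = (beta, se, p, p < alpha)
        except ConvergenceError:
            logger.warning("screen_features: univariate fit failed for %s", name)
            rows[name] = (np.nan, np.nan, np.nan, False)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["beta", "se", "p", "retained"])
    out.index.name = "feature"
    out["retained"] = out["retained"].astype(bool)
    return out


def prune_collinear(fm_scaled: pd.DataFrame, features: list[str],
                    univariate_p: pd.Series, threshold: float = 0.95,
                    ) -> list[str]:
    """Drop one of each feature pair with |Pearson r| > threshold, keeping
    the feature with the smaller univariate p."""
    feats = sorted(features, key=lambda f: (univariate_p.get(f, np.inf)))
    kept: list[str] = []
    for f in feats:
        x = fm_scaled[f]
        redundant = False
        for g in kept:
            r = x.corr(fm_scaled[g])
            if np.isfinite(r) and abs(r) > threshold:
                redundant = True
                break
        if not redundant:
            kept.append(f)
    # restore catalogue order
    order = {name: i for i, name in enumerate(fm_scaled.columns)}
    return sorted(kept, key=lambda f: order[f])


@dataclasses.dataclass
class CutpointResult:
    """Outcome of the minimum-p-value cut-point scan."""

    cutoff: float
    candidates: np.ndarray
    statistics: np.ndarray
    pvalues: np.ndarray
    p_min: float
    p_corrected: float
    min_group_frac: float

    def as_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "p_min": self.p_min,
            "p_corrected": self.p_corrected,
            "min_group_frac": self.min_group_frac,
            "n_candidates": int(len(self.candidates)),
        }


def _miller_siegmund(p_min: float, eps_low: float, eps_high: float) -> float:
    """Correct a minimum p-value selected over cut-points restricted to the
    (eps_low, 1-eps_high) quantile band of the score distribution."""
    if p_min <= 0:
        return 0.0
    z = stats.norm.isf(p_min / 2.0)
    if not np.isfinite(z) or z <= 1.0:
        return 1.0
    phi = stats.norm.pdf(z)
    span = np.log(((1.0 - eps_low) * (1.0 - eps_high)) / (eps_low * eps_high))
    p_cor = phi * (z - 1.0 / z) * span + 4.0 * phi / z
    return float(min(1.0, max(p_cor, p_min)))


def optimal_cutpoint(scores: np.ndarray | pd.Series, cohort: pd.DataFrame,
                     min_group_frac: float = 0.1, endpoint: str = "bcss",
                     ) -> CutpointResult:
    """Minimum-p-value cut-point for dichotomizing a continuous score.

    Candidates are the midpoints between consecutive distinct score values;
    only candidates leaving at least ``min_group_frac`` of patients in each
    group are scanned.  For each candidate a two-group log-rank test is
    computed; the cut-off attaining the smallest p wins (ties broken toward
    the lower cut-off).  The reported ``p_corrected`` applies the
    Miller-Siegmund adjustment for the optimism of minimum-p selection; the
    selection itself uses the raw minimum p.
    """
    scores = np.asarray(scores, dtype=float)
    tcol, ecol = surv.endpoint_columns(endpoint)
    time = cohort[tcol].to_numpy(dtype=float)
    event = cohort[ecol].to_numpy(dtype=int)
    if scores.size != len(cohort):
        raise ValueError("scores and cohort are not aligned")
    if event.sum() == 0:
        raise ValueError("cut-point scan needs at least one event")
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValueError("cut-point scan needs >= 2 distinct scores")

    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    n = scores.size
    min_n = int(np.ceil(min_group_frac * n))
    n_low = np.searchsorted(np.sort(scores), candidates, side="right")
    ok = (n_low >= min_n) & ((n - n_low) >= min_n)
    candidates = candidates[ok]
    if candidates.size == 0:
        raise ValueError("no candidate cut-point satisfies the group-size "
                         f"constraint (min_group_frac={min_group_frac})")

    stats_arr = np.empty(candidates.size)
    pvals = np.empty(candidates.size)
    for k, c in enumerate(candidates):
        labels = scores > c
        stats_arr[k], pvals[k] = surv.logrank_test(time, event, labels)

    best = int(np.argmin(pvals))  # argmin takes the first (lowest) candidate on ties
    p_min = float(pvals[best])
    frac_low = n_low[ok][best] / n
    p_cor = _miller_siegmund(p_min, min_group_frac, min_group_frac)
    return CutpointResult(
        cutoff=float(candidates[best]),
        candidates=candidates,
        statistics=stats_arr,
        pvalues=pvals,
        p_min=p_min,
        p_corrected=p_cor,
        min_group_frac=min_group_frac,
    )


def dichotomize(scores: np.ndarray | pd.Series, cutoff: float) -> np.ndarray:
    """Label scores strictly above the cut-off as the heterogeneous ('high')
    group; scores at or below it are 'low'."""
    if not np.isfinite(cutoff):
        raise ValueError("cut-off must be finite")
    scores = np.asarray(scores, dtype=float)
    return np.where(scores > cutoff, "high", "low")


class ITHScoreModel:
    """Overall intra-tumor heterogeneity score model.

    Parameters
    ----------
    features : DataFrame
        Raw (unscaled) patients x features table, indexed by patient id.
    cohort : DataFrame
        Survival table with ``patient_id``, ``time_months``, ``event`` (and
        optionally the DMFS-style endpoint columns).
    catalogue : FeatureCatalogue, optional
        Feature definitions; defaults to the 162-feature catalogue.  Used
        for the family scores.
    intercept : float
        The constant offset ``a`` of the score; 0 by default.

    Examples
    --------
    >>> model = ITHScoreModel(feature_matrix, cohort)
    >>> res = model.fit(alpha=0.05)
    >>> res.summary()            # doctest: +SKIP
    """

    def __init__(self, features: pd.DataFrame, cohort: pd.DataFrame,
                 catalogue: FeatureCatalogue | None = None,
                 endpoint: str = "bcss", intercept: float = 0.0):
        surv.validate_cohort(cohort, endpoint)
        ids = cohort["patient_id"]
        missing = ids[~ids.isin(features.index)]
        if len(missing):
            raise ValueError(f"cohort patients missing from feature matrix: "
                             f"{missing.tolist()[:5]}")
        self.features = features.loc[ids].copy()
        self.cohort = cohort.reset_index(drop=True)
        self.catalogue = catalogue if catalogue is not None else default_catalogue()
        self.endpoint = endpoint
        self.intercept = float(intercept)

    @classmethod
    def from_stacks(cls, stacks, cohort: pd.DataFrame, catalogue=None,
                    **kwargs) -> "ITHScoreModel":
        """Build the model straight from layer stacks (runs DCIS exclusion,
        patch extraction and the feature catalogue)."""
        from .catalogue import compute_feature_matrix
        from .preprocess import exclude_dcis

        cat = catalogue if catalogue is not None else default_catalogue()
        fm = compute_feature_matrix([exclude_dcis(s) for s in stacks], cat)
        return cls(fm, cohort, catalogue=cat, **kwargs)

    def fit(self, alpha: float = 0.05, min_group_frac: float = 0.1,
            corr_threshold: float = 0.95, ridge_fallback: float = 0.01,
            ) -> "ITHScoreResults":
        """Run screening, the multivariable Cox fit, scoring and the
        cut-point scan; returns an :class:`ITHScoreResults`."""
        scaled, bounds = scale_features(self.features)
        screening = screen_features(scaled, self.cohort, alpha=alpha,
                                    endpoint=self.endpoint)
        retained = screening.index[screening["retained"]].tolist()
        if not retained:
            raise ValueError(f"no feature passed univariate screening at "
                             f"alpha={alpha}")
        pruned = prune_collinear(scaled, retained, screening["p"],
                                 threshold=corr_threshold)

        tcol, ecol = surv.endpoint_columns(self.endpoint)
        n_events = int(self.cohort[ecol].sum())

        X = scaled[pruned].copy()
        # pairwise-complete is not possible in one partial likelihood;
        # impute residual missing values at the cohort feature mean
        X = X.fillna(X.mean())
        df = pd.concat([self.cohort[[tcol, ecol]].set_axis(X.index), X], axis=1)

        penalty = 0.0
        if n_events < 10 * len(pruned):
            # ill-posed multivariable fit: choose the ridge strength by
            # cross-validated partial likelihood instead of trusting the
            # raw maximum-likelihood coefficients
            penalty = self._select_ridge(df, tcol, ecol)
            logger.warning("fit: %d events for %d covariates (<10 per "
                           "covariate); using CV-selected ridge penalty %g",
                           n_events, len(pruned), penalty)
        fit = self._fit_cox(df, tcol, ecol, penalty, ridge_fallback)

        betas = fit.params
        scores = pd.Series(
            self.intercept + X.to_numpy() @ betas.to_numpy(),
            index=self.cohort["patient_id"].to_numpy(), name="ith_score",
        )
        cut = optimal_cutpoint(scores.to_numpy(), self.cohort,
                               min_group_frac=min_group_frac,
                               endpoint=self.endpoint)
        groups = pd.Series(dichotomize(scores.to_numpy(), cut.cutoff),
                           index=scores.index, name="ith_group")

        fam_scores = pd.DataFrame({
            fam: family_score(scaled, self.catalogue, fam)
            for fam in ("differentiation", "stroma", "tils")
            if any(n in scaled.columns for n in self.catalogue.family_members(fam))
        })
        fam_scores.index = scores.index

        return ITHScoreResults(
            model=self, scaled=scaled, bounds=bounds, screening=screening,
            screened=retained, pruned=pruned, cox=fit, params=betas,
            bse=fit.bse, scores=scores, cutpoint=cut, groups=groups,
            family_scores=fam_scores, alpha=alpha, penalty=fit.penalty,
        )

    @staticmethod
    def _select_ridge(df: pd.DataFrame, tcol: str, ecol: str,
                      grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
                      k: int = 3) -> float:
        from lifelines.utils import k_fold_cross_validation

        dfr = df.reset_index(drop=True)
        best, best_ll = grid[0], -np.inf
        for pen in grid:
            try:
                lls = k_fold_cross_validation(
                    CoxPHFitter(penalizer=pen), dfr, tcol, ecol, k=k,
                    seed=0, scoring_method="log_likelihood")
            except ConvergenceError:
                continue
            ll = float(np.mean(lls))
            if ll > best_ll:
                best, best_ll = pen, ll
        return best

    @staticmethod
    def _fit_cox(df: pd.DataFrame, tcol: str, ecol: str, penalty: float,
                 ridge_fallback: float) -> surv.CoxFit:
        covs = [c for c in df.columns if c not in (tcol, ecol)]
        df = df.reset_index(drop=True)
        df.insert(0, "patient_id", np.arange(len(df)))
        try:
            return surv.cox_fit(df, covs, penalty=penalty)
        except ConvergenceError:
            logger.warning("multivariable Cox did not converge; retrying "
                           "with ridge penalty %.3g", ridge_fallback)
            return surv.cox_fit(df, covs, penalty=max(penalty, ridge_fallback))


@dataclasses.dataclass
class ITHScoreResults:
    """Fitted overall-ITH score: estimates, groups and diagnostics."""

    model: ITHScoreModel
    scaled: pd.DataFrame
    bounds: pd.DataFrame
    screening: pd.DataFrame
    screened: list[str]
    pruned: list[str]
    cox: surv.CoxFit
    params: pd.Series
    bse: pd.Series
    scores: pd.Series
    cutpoint: CutpointResult
    groups: pd.Series
    family_scores: pd.DataFrame
    alpha: float
    penalty: float

    # -- derived quantities -------------------------------------------------
    def predict(self, features_new: pd.DataFrame) -> pd.Series:
        """Score new patients on the training scale (clipped to [0, 100]
        per feature before weighting)."""
        cols = self.params.index
        lo = self.bounds["min"]
        hi = self.bounds["max"]
        X = features_new[cols]
        Xs = ((X - lo[cols]) / (hi[cols] - lo[cols]) * 100.0).clip(0, 100)
        Xs = Xs.fillna(self.scaled[cols].mean())
        return pd.Series(
            self.model.intercept + Xs.to_numpy() @ self.params.to_numpy(),
            index=features_new.index, name="ith_score",
        )

    def group_logrank(self) -> tuple[float, float]:
        """Log-rank test between the dichotomized low/high groups."""
        tcol, ecol = surv.endpoint_columns(self.model.endpoint)
        return surv.logrank_test(self.model.cohort[tcol],
                                 self.model.cohort[ecol],
                                 self.groups.to_numpy())

    def group_hazard_ratio(self) -> surv.CoxFit:
        """Cox fit of the high-vs-low group indicator (HR of high ITH)."""
        df = self.model.cohort.copy()
        df["high_ith"] = (self.groups.to_numpy() == "high").astype(float)
        return surv.cox_fit(df, ["high_ith"], endpoint=self.model.endpoint)

    def km_curves(self):
        """Kaplan-Meier curves of the low/high groups."""
        return surv.km_estimate(self.model.cohort, group=self.groups.to_numpy(),
                                endpoint=self.model.endpoint)

    def plot_km(self, ax=None):
        """Plot the low/high Kaplan-Meier curves (step functions)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, curve in sorted(self.km_curves().items()):
            ax.step(curve.times, curve.survival, where="post",
                    label=f"{label} ITH (n={int(curve.at_risk[0])})")
        ax.set_xlabel("time (months)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        stat, p = self.group_logrank()
        hr = self.group_hazard_ratio()
        lines = [
            "Overall ITH score model",
            "=" * 60,
            f"patients: {len(self.scores)}    "
            f"events: {self.cox.n_events}    endpoint: {self.model.endpoint}",
            f"features: {self.scaled.shape[1]} scaled, "
            f"{len(self.screened)} screened (alpha={self.alpha}), "
            f"{len(self.pruned)} in Cox fit (penalty={self.penalty:g})",
            f"cut-off: {self.cutpoint.cutoff:.4g}   "
            f"min-p: {self.cutpoint.p_min:.3g}   "
            f"corrected p: {self.cutpoint.p_corrected:.3g}",
            f"high-ITH group: {(self.groups == 'high').sum()} patients, "
            f"HR {hr.hazard_ratios.iloc[0]:.3g} "
            f"(95% CI {hr.conf_int.iloc[0, 0]:.3g}-{hr.conf_int.iloc[0, 1]:.3g})",
            f"low/high log-rank: chi2={stat:.3g}, p={p:.3g}",
            "-" * 60,
            "top Cox-weighted features:",
        ]
        top = self.params.abs().sort_values(ascending=False).head(10).index
        for name in top:
            lines.append(f"  {name:<42s} beta={self.params[name]: .4f} "
                         f"se={self.bse[name]:.4f}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "features": list(self.params.index),
            "betas": self.params.tolist(),
            "intercept": self.model.intercept,
            "cutoff": self.cutpoint.cutoff,
            "alpha": self.alpha,
            "penalty": self.penalty,
            "endpoint": self.model.endpoint,
            "cutpoint": self.cutpoint.as_dict(),
            "scale_bounds": {
                "min": self.bounds["min"].to_dict(),
                "max": self.bounds["max"].to_dict(),
            },
            "n_screened": len(self.screened),
            "n_features_total": int(self.model.features.shape[1]),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
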