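"""Survival machinery: Cox fits, Harrell's C, Kaplan-Meier, log-rank,
and score dichotomization (median, constrained optimal cut-point, fixed
threshold).

Cox models are fitted with lifelines (Efron tie handling).  Harrell's C is
computed by direct pair counting so that a Noether-type confidence interval
can be attached.  The dichotomizers all return a :class:`DichotomyResult`
carrying the threshold, group sizes, the log-rank comparison, and per-group
Kaplan-Meier summaries (including the distant-recurrence-free fraction at
five years, the study's clinically quoted horizon).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import norm

from .containers import check_outcome

__all__ = [
    "CoxFitResult",
    "DichotomyResult",
    "cox_fit",
    "harrells_c",
    "km_estimate",
    "logrank_test",
    "median_dichotomize",
    "optimal_cutpoint",
    "apply_threshold",
]


@dataclass
class CoxFitResult:
    """Summary of a Cox proportional-hazards fit."""

    coefficients: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    wald_p: pd.Series
    lr_p: float
    concordance: float
    concordance_ci: tuple
    n: int
    n_events: int
    n_dropped: int = 0
    separation_flag: bool = False

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "HR_lower95": self.ci_lower,
                "HR_upper95": self.ci_upper,
                "wald_p": self.wald_p,
            }
        )


@dataclass
class KMCurve:
    """Product-limit estimate with an S(t) lookup (events at times ≤ t count)."""

    table: pd.DataFrame = field(repr=False)  # time, at_risk, events, survival
    n: int = 0
    n_events: int = 0
    max_time: float = 0.0

    def survival_at(self, t: float) -> float:
        rows = self.table[self.table["time"] <= t]
        return float(rows["survival"].iloc[-1]) if len(rows) else 1.0

    def extrapolated_at(self, t: float) -> bool:
        return t > self.max_time


@dataclass
class DichotomyResult:
    """Two-group split of a score with its survival comparison."""

    threshold: float
    groups: pd.Series = field(repr=False)  # "low" / "high" per sample
    n_low: int = 0
    n_high: int = 0
    logrank_stat: float = float("nan")
    logrank_p: float = float("nan")
    km_low: KMCurve = None
    km_high: KMCurve = None
    drfree_5y_low: float = float("nan")
    drfree_5y_high: float = float("nan")
    n_dropped: int = 0
    warning: str = ""


def _complete(scores, outcome):
    scores = pd.Series(scores, dtype=float)
    outcome = check_outcome(outcome)
    aligned = outcome.loc[scores.index]
    keep = scores.notna()
    return scores[keep], aligned.loc[keep], int((~keep).sum())


def cox_fit(x, outcome: pd.DataFrame, alpha: float = 0.05) -> CoxFitResult:
    """Fit a Cox proportional-hazards model (Efron ties) via lifelines.

    Parameters
    ----------
    x : Series or DataFrame
        One or more covariates indexed by sample.  Samples missing any
        covariate are dropped (complete cases) and counted in
        ``n_dropped``.
    outcome : DataFrame
        Must carry ``time`` and ``event`` columns on the same index.

    Returns a :class:`CoxFitResult` with per-covariate HRs and Wald CIs,
    the model likelihood-ratio P against the null, and Harrell's C of the
    linear predictor.
    """
    X = pd.DataFrame(x).astype(float)
    outcome = check_outcome(outcome)
    df = X.join(outcome[["time", "event"]], how="inner")
    n_total = len(df)
    df = df.dropna()
    n_dropped = n_total - len(df)
    if int(df["event"].sum()) == 0:
        raise ValueError("cox_fit: no events in the analysis set")
    if int(df["event"].sum()) < 2:
        raise ValueError("cox_fit: fewer than two events")

    fitter = CoxPHFitter()
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fitter.fit(df, duration_col="time", event_col="event",
                   fit_options={"precision": 1e-12})
        separation = any("convergence" in str(w.message).lower() or
                         "complete separation" in str(w.message).lower()
                         for w in caught)
    summ = fitter.summary
    coefs = summ["coef"]
    if (coefs.abs() > 20).any():
        separation = True
    lr_p = float(fitter.log_likelihood_ratio_test().p_value)

    lp = pd.Series(np.dot(df[X.columns], coefs.values), index=df.index)
    if lp.nunique() > 1:
        c, c_ci = harrells_c(lp, df)
    else:  # e.g. capped/degenerate fit
        c, c_ci = 0.5, (float("nan"), float("nan"))
    return CoxFitResult(
        coefficients=coefs,
        hazard_ratios=summ["exp(coef)"],
        ci_lower=summ["exp(coef) lower 95%"],
        ci_upper=summ["exp(coef) upper 95%"],
        wald_p=summ["p"],
        lr_p=lr_p,
        concordance=c,
        concordance_ci=c_ci,
        n=len(df),
        n_events=int(df["event"].sum()),
        n_dropped=n_dropped,
        separation_flag=separation,
    )


def harrells_c(score, outcome: pd.DataFrame, alpha: float = 0.05):
    """Harrell's concordance of a risk score with censored event times.

    A pair (i, j) is comparable when the earlier time is an event and the
    times differ (pairs with tied times are excluded).  Higher score is
    expected for the earlier event; tied scores count half.  The CI is the
    Noether-type normal approximation ``C ± z·sqrt(C(1−C)/m)`` with *m*
    comparable pairs.
    """
    s = pd.Series(score, dtype=float)
    outcome = check_outcome(outcome).loc[s.index]
    t = outcome["time"].to_numpy(float)
    e = outcome["event"].to_numpy(int)
    x = s.to_numpy(float)
    # ordered pairs (i, j): i an event, j surviving past t_i
    comparable = (e[:, None] == 1) & (t[None, :] > t[:, None])
    comp = int(comparable.sum())
    conc = int((comparable & (x[:, None] > x[None, :])).sum())
    tied = int((comparable & (x[:, None] == x[None, :])).sum())
    if comp == 0:
        raise ValueError("harrells_c: no comparable pairs")
    c = (conc + 0.5 * tied) / comp
    se = float(np.sqrt(max(c * (1 - c), 1e-12) / comp))
    z = norm.ppf(1 - alpha / 2)
    return float(c), (max(0.0, c - z * se), min(1.0, c + z * se))


def km_estimate(outcome: pd.DataFrame, group=None) -> KMCurve:
    """Kaplan-Meier product-limit estimate for a (sub)cohort."""
    outcome = check_outcome(outcome)
    if group is not None:
        outcome = outcome.loc[group]
    if len(outcome) == 0:
        raise ValueError("km_estimate: empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(outcome["time"], outcome["event"])
    ev = kmf.event_table
    table = pd.DataFrame(
        {
            "time": ev.index.to_numpy(float),
            "at_risk": ev["at_risk"].to_numpy(int),
            "events": ev["observed"].to_numpy(int),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(float),
        }
    )
    return KMCurve(
        table=table,
        n=len(outcome),
        n_events=int(outcome["event"].sum()),
        max_time=float(outcome["time"].max()),
    )


def logrank_test(outcome: pd.DataFrame, groups: pd.Series):
    """Two-group log-rank chi-square (df = 1) and P."""
    outcome = check_outcome(outcome)
    groups = pd.Series(groups).loc[outcome.index]
    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError(f"logrank_test needs exactly 2 groups, got {len(labels)}")
    a = outcome[groups == labels[0]]
    b = outcome[groups == labels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("logrank_test: empty group")
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def _dichotomy(scores, outcome, threshold, n_dropped=0, warn_empty=False):
    groups = pd.Series(np.where(scores <= threshold, "low", "high"), index=scores.index)
    n_low = int((groups == "low").sum())
    n_high = int((groups == "high").sum())
    res = DichotomyResult(threshold=float(threshold), groups=groups,
                          n_low=n_low, n_high=n_high, n_dropped=n_dropped)
    if n_low == 0 or n_high == 0:
        if not warn_empty:
            raise ValueError("dichotomization produced an empty group")
        res.warning = "one group is empty; log-rank P undefined"
        warnings.warn(res.warning)
        if n_low:
            res.km_low = km_estimate(outcome, groups == "low")
            res.drfree_5y_low = res.km_low.survival_at(5.0)
        if n_high:
            res.km_high = km_estimate(outcome, groups == "high")
            res.drfree_5y_high = res.km_high.survival_at(5.0)
        return res
    res.logrank_stat, res.logrank_p = logrank_test(outcome, groups)
    res.km_low = km_estimate(outcome, groups == "low")
    res.km_high = km_estimate(outcome, groups == "high")
    res.drfree_5y_low = res.km_low.survival_at(5.0)
    res.drfree_5y_high = res.km_high.survival_at(5.0)
    return res


def median_dichotomize(scores, outcome: pd.DataFrame) -> DichotomyResult:
    """Split at the median score; ties at the median go to the low group."""
    s, y, dropped = _complete(scores, outcome)
    if s.nunique() < 2:
        raise ValueError("median_dichotomize: all scores identical")
    return _dichotomy(s, y, float(np.median(s)), n_dropped=dropped)


def optimal_cutpoint(scores, outcome: pd.DataFrame, min_frac: float = 0.20) -> DichotomyResult:
    """Threshold minimizing the log-rank P subject to a group-size floor.

    Candidate thresholds are the midpoints between consecutive distinct
    scores; a candidate is feasible when both groups hold at least
    ``min_frac`` of the analysis samples.  Ties on P resolve to the
    smaller threshold.
    """
    s, y, dropped = _complete(scores, outcome)
    n = len(s)
    distinct = np.unique(s.to_numpy())
    if len(distinct) < 2:
        raise ValueError("optimal_cutpoint: all scores identical")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for thr in mids:
        n_low = int((s <= thr).sum())
        n_high = n - n_low
        if n_low < min_frac * n or n_high < min_frac * n:
            continue
        groups = pd.Series(np.where(s <= thr, "low", "high"), index=s.index)
        _, p = logrank_test(y, groups)
        if best is None or p < best[1] - 1e-15:
            best = (thr, p)
    if best is None:
        raise ValueError(
            f"optimal_cutpoint: no threshold leaves both groups >= {min_frac:.0%} of n"
        )
    return _dichotomy(s, y, best[0], n_dropped=dropped)


def apply_threshold(scores, threshold: float, outcome: pd.DataFrame) -> DichotomyResult:
    """Dichotomize at a fixed, externally supplied threshold.

    Supports cut-point transfer across cohorts and platforms; if the
    threshold strands all samples on one side the result is returned with
    an undefined P and a warning rather than an error.
    """
    if not np.isfinite(threshold):
        raise ValueError("apply_threshold: threshold must be finite")
    s, y, dropped = _complete(scores, outcome)
    return _dichotomy(s, y, float(threshold), n_dropped=dropped, warn_empty=True)
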