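"""Survival estimation for competing-cause mortality cohorts.

Implements the estimation layer for all-cause and cause-specific
mortality with three competing cause-of-death labels (CVD, cancer,
other):

* Kaplan–Meier all-cause survival and Aalen–Johansen cause-specific
  cumulative incidence, computed from a shared risk-set table so the
  accounting identity ``1 - KM(t) = sum_k CIF_k(t)`` holds to machine
  precision at every event time;
* cause-specific Cox proportional-hazards models (deaths from competing
  causes censored at their death time), with the frailty index entered
  either per 0.1 increment or as pre-frail/frail indicators against a
  robust reference;
* Harrell's concordance index with an asymptotic confidence interval;
* scaled-Schoenfeld proportional-hazards tests and likelihood-ratio
  tests for frailty-by-moderator interactions.

Partial-likelihood fitting (Efron tie handling) and the Schoenfeld
residual machinery are delegated to :mod:`lifelines`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from .simulate import CAUSES

__all__ = [
    "CENSORED",
    "StepCurve",
    "ConcordanceResult",
    "HazardFitResult",
    "LRTResult",
    "validate_outcomes",
    "kaplan_meier",
    "aalen_johansen",
    "build_model_frame",
    "fit_cause_specific_cox",
    "harrells_c",
    "ph_test",
    "lrt_interaction",
]

CENSORED = "censored"
_VALID_CAUSES = set(CAUSES) | {CENSORED}


class NoEventsError(ValueError):
    """Raised when a fit or estimator is requested on data without events."""


# ---------------------------------------------------------------------------
# nonparametric estimators


@dataclass(frozen=True)
class StepCurve:
    """Right-continuous step function (survival or cumulative incidence)."""

    times: np.ndarray
    values: np.ndarray
    initial: float
    label: str = ""

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if len(self.times) == 0:
            out = np.full(t.shape, self.initial)
        else:
            idx = np.searchsorted(self.times, t, side="right") - 1
            out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.initial)
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": np.concatenate([[0.0], self.times]),
                "estimate": np.concatenate([[self.initial], self.values]),
            }
        )


def validate_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Check an outcomes table (time, cause) and return it."""
    t = outcomes["time"].to_numpy(float)
    if not np.isfinite(t).all() or (t < 0).any():
        raise ValueError("times must be finite and non-negative")
    bad = set(outcomes["cause"]) - _VALID_CAUSES
    if bad:
        raise ValueError(f"unknown cause labels {sorted(bad)}; expected {_VALID_CAUSES}")
    return outcomes


def _risk_table(time: np.ndarray, cause: np.ndarray) -> pd.DataFrame:
    """Per-death-time risk sets: at-risk count and deaths by cause.

    Persons censored at a death time are counted as still at risk there
    (deaths processed before censorings at tied times).
    """
    dead = cause != CENSORED
    utimes = np.unique(time[dead])
    order = np.sort(time)
    n_at_risk = len(time) - np.searchsorted(order, utimes, side="left")
    tab = pd.DataFrame({"time": utimes, "n_risk": n_at_risk})
    deaths = pd.crosstab(time[dead], cause[dead]).reindex(
        index=utimes, columns=list(CAUSES), fill_value=0
    )
    for k in CAUSES:
        tab[f"d_{k}"] = deaths[k].to_numpy()
    tab["d_all"] = tab[[f"d_{k}" for k in CAUSES]].sum(axis=1)
    return tab


def kaplan_meier(outcomes: pd.DataFrame) -> StepCurve:
    """Product-limit estimate of all-cause survival.

    Deaths from any cause are events; a cohort with no deaths yields the
    constant curve S(t) = 1 with a warning.
    """
    validate_outcomes(outcomes)
    time = outcomes["time"].to_numpy(float)
    cause = outcomes["cause"].to_numpy(object)
    tab = _risk_table(time, cause)
    if tab.empty:
        warnings.warn("no deaths observed; survival curve is constant 1")
        return StepCurve(np.array([]), np.array([]), 1.0, label="km")
    surv = np.cumprod(1.0 - tab["d_all"].to_numpy() / tab["n_risk"].to_numpy())
    return StepCurve(tab["time"].to_numpy(), surv, 1.0, label="km")


def aalen_johansen(
    outcomes: pd.DataFrame,
    cause: str,
    groups: Optional[pd.Series] = None,
) -> StepCurve | dict[object, StepCurve]:
    """Aalen–Johansen cumulative incidence of one cause.

    ``CIF_k(t) = sum over death times t_i <= t of S(t_i-) d_{k,i}/n_i``
    with S the all-cause Kaplan–Meier survival.  When ``groups`` is given
    (e.g. frailty category), one curve per non-empty group is returned;
    empty groups are omitted with a warning.
    """
    if cause not in CAUSES:
        raise ValueError(f"cause must be one of {CAUSES}, got {cause!r}")
    if groups is not None:
        out: dict[object, StepCurve] = {}
        for g in pd.unique(groups.dropna()):
            sub = outcomes[groups.to_numpy() == g]
            if sub.empty:
                warnings.warn(f"group {g!r} is empty; omitted")
                continue
            out[g] = aalen_johansen(sub, cause)
        return out
    validate_outcomes(outcomes)
    time = outcomes["time"].to_numpy(float)
    cvec = outcomes["cause"].to_numpy(object)
    tab = _risk_table(time, cvec)
    if tab.empty:
        return StepCurve(np.array([]), np.array([]), 0.0, label=f"cif_{cause}")
    n_risk = tab["n_risk"].to_numpy(float)
    d_all = tab["d_all"].to_numpy(float)
    surv = np.cumprod(1.0 - d_all / n_risk)
    surv_minus = np.concatenate([[1.0], surv[:-1]])
    inc = surv_minus * tab[f"d_{cause}"].to_numpy(float) / n_risk
    return StepCurve(tab["time"].to_numpy(), np.cumsum(inc), 0.0, label=f"cif_{cause}")


# ---------------------------------------------------------------------------
# Harrell's concordance


@dataclass(frozen=True)
class ConcordanceResult:
    """Concordance index with asymptotic 95% confidence interval."""

    c: float
    ci_low: float
    ci_high: float
    se: float
    n_comparable_pairs: int


def harrells_c(
    risk_scores: np.ndarray | pd.Series,
    time: np.ndarray | pd.Series,
    event: np.ndarray | pd.Series,
    *,
    alpha: float = 0.05,
    chunk: int = 512,
) -> ConcordanceResult:
    """Harrell's C for right-censored data.

    A pair is comparable when the strictly shorter time ends in an event;
    it is concordant when the shorter-lived member has the higher risk
    score, with tied scores counting one half.  The confidence interval
    uses the influence-function (asymptotic U-statistic) variance of the
    concordant/comparable ratio.

    Raises
    ------
    NoEventsError
        When no pair is comparable (e.g. everyone censored).
    """
    r = np.asarray(risk_scores, float)
    t = np.asarray(time, float)
    e = np.asarray(event, bool)
    n = len(r)
    if not (len(t) == len(e) == n):
        raise ValueError("risk_scores, time and event must have equal length")
    h = np.zeros(n)  # per-subject concordant (+0.5 tie) pair weight
    g = np.zeros(n)  # per-subject comparable pair count
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        ti, ri, ei = t[sl, None], r[sl, None], e[sl, None]
        i_short = (ti < t[None, :]) & ei  # i died first
        j_short = (t[None, :] < ti) & e[None, :]
        conc_i = (ri > r[None, :]) + 0.5 * (ri == r[None, :])
        pair_h = i_short * conc_i + j_short * (1.0 - conc_i)
        pair_g = i_short | j_short
        h[sl] += pair_h.sum(axis=1)
        g[sl] += pair_g.sum(axis=1)
    total_g = g.sum()  # each pair counted once from each side
    if total_g == 0:
        raise NoEventsError(
            "no comparable pairs: need at least one event with a strictly "
            "shorter time than another record"
        )
    c = float(h.sum() / total_g)
    # influence function of a ratio of degree-2 U-statistics
    gbar = g / (n - 1)
    hbar = h / (n - 1)
    ud = total_g / (n * (n - 1))
    psi = 2.0 * (hbar - c * gbar) / ud
    se = float(psi.std(ddof=1) / np.sqrt(n))
    zq = stats.norm.ppf(1 - alpha / 2)
    return ConcordanceResult(
        c=c,
        ci_low=float(max(0.0, c - zq * se)),
        ci_high=float(min(1.0, c + zq * se)),
        se=se,
        n_comparable_pairs=int(round(total_g / 2)),
    )


# ---------------------------------------------------------------------------
# cause-specific Cox models


ADJUSTERS_DEFAULT = ("sex", "living_alone", "education")


def build_model_frame(
    data: pd.DataFrame,
    *,
    fi_param: str = "per01",
    adjusters: Sequence[str] = ADJUSTERS_DEFAULT,
    adjust_age: bool = False,
    interactions_with: Optional[str] = None,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Design matrix for the mortality models.

    ``fi_param='per01'`` enters the frailty index as FI/0.1 (one hazard
    ratio per 0.1 FI increment); ``'categories'`` enters pre-frail and
    frail indicators with robust as the reference.  Sex enters as a
    female indicator, education as medium/high dummies against low, and
    ``interactions_with`` adds FI-by-moderator product terms (moderator
    in {'sex', 'education'}).

    Returns (frame, fi_term_names, interaction_term_names); the frame
    also carries ``time`` and the original ``cause`` column.
    """
    if fi_param not in ("per01", "categories"):
        raise ValueError("fi_param must be 'per01' or 'categories'")
    df = pd.DataFrame(index=data.index)
    df["time"] = data["time"].astype(float)
    df["cause"] = data["cause"]
    if fi_param == "per01":
        df["fi_per_0.1"] = data["fi"].astype(float) / 0.1
        fi_terms = ["fi_per_0.1"]
    else:
        cat = data["category"]
        df["pre_frail"] = (cat == "pre_frail").astype(float)
        df["frail"] = (cat == "frail").astype(float)
        fi_terms = ["pre_frail", "frail"]
    if "sex" in adjusters:
        df["female"] = (data["sex"] == "female").astype(float)
    if "living_alone" in adjusters:
        df["living_alone"] = (data["living_alone"] == "yes").astype(float)
    if "education" in adjusters:
        df["educ_medium"] = (data["education"] == "medium").astype(float)
        df["educ_high"] = (data["education"] == "high").astype(float)
    if adjust_age:
        df["age"] = data["age"].astype(float)
    inter_terms: list[str] = []
    if interactions_with is not None:
        if interactions_with == "sex":
            mods = ["female"]
        elif interactions_with == "education":
            mods = ["educ_medium", "educ_high"]
        else:
            raise ValueError("interactions_with must be 'sex' or 'education'")
        for fi_term in fi_terms:
            for m in mods:
                name = f"{fi_term}:{m}"
                df[name] = df[fi_term] * df[m]
                inter_terms.append(name)
    df = df.dropna()
    return df, fi_terms, inter_terms


@dataclass
class HazardFitResult:
    """One cause-specific (or all-cause) Cox fit."""

    target_cause: str
    fi_param: str
    coefficients: pd.DataFrame  # index: covariate; HR with 95% CI, SE, p
    concordance: Optional[ConcordanceResult]
    n: int
    n_events: int
    log_likelihood: float
    ph_pvalues: Optional[Mapping[str, float]] = None
    model: CoxPHFitter = field(default=None, repr=False)
    frame: pd.DataFrame = field(default=None, repr=False)

    def hr(self, covariate: str) -> float:
        return float(self.coefficients.loc[covariate, "hr"])


def _event_indicator(cause: pd.Series, target_cause: str) -> pd.Series:
    if target_cause == "all_cause":
        return (cause != CENSORED).astype(int)
    if target_cause not in CAUSES:
        raise ValueError(
            f"target_cause must be 'all_cause' or one of {CAUSES}, got {target_cause!r}"
        )
    return (cause == target_cause).astype(int)


def fit_cause_specific_cox(
    data: pd.DataFrame,
    target_cause: str = "all_cause",
    *,
    fi_param: str = "per01",
    adjusters: Sequence[str] = ADJUSTERS_DEFAULT,
    adjust_age: bool = False,
    compute_concordance: bool = True,
    compute_ph: bool = False,
) -> HazardFitResult:
    """Cause-specific Cox proportional-hazards fit.

    Deaths from the target cause are events; deaths from competing causes
    are censored at their death time (for ``'all_cause'`` every death is
    an event).  Ties are handled with the Efron approximation.  The
    concordance is Harrell's C of the model's linear predictor.

    Raises
    ------
    NoEventsError
        When the target cause has zero events in ``data``.
    """
    frame, fi_terms, _ = build_model_frame(
        data, fi_param=fi_param, adjusters=adjusters, adjust_age=adjust_age
    )
    frame = frame.assign(event=_event_indicator(frame["cause"], target_cause))
    n_events = int(frame["event"].sum())
    if n_events == 0:
        raise NoEventsError(f"no events for target cause {target_cause!r}")
    fit_df = frame.drop(columns=["cause"])
    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col="time", event_col="event")
    summ = cph.summary
    coefficients = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": summ["exp(coef)"],
            "hr_ci_low": summ["exp(coef) lower 95%"],
            "hr_ci_high": summ["exp(coef) upper 95%"],
            "se": summ["se(coef)"],
            "p": summ["p"],
        }
    )
    conc = None
    if compute_concordance:
        lp = cph.predict_log_partial_hazard(fit_df).to_numpy()
        conc = harrells_c(lp, frame["time"], frame["event"].astype(bool))
    result = HazardFitResult(
        target_cause=target_cause,
        fi_param=fi_param,
        coefficients=coefficients,
        concordance=conc,
        n=len(frame),
        n_events=n_events,
        log_likelihood=float(cph.log_likelihood_),
        model=cph,
        frame=fit_df,
    )
    if compute_ph:
        result.ph_pvalues = ph_test(result)
    return result


def ph_test(
    fit: HazardFitResult, *, time_transform: str = "km"
) -> dict[str, float]:
    """Scaled-Schoenfeld proportional-hazards test for a fitted model.

    Score test of zero slope of each covariate's scaled Schoenfeld
    residuals against transformed time (Kaplan–Meier transform by
    default, ``'identity'`` available); the global test sums the
    per-covariate chi-squares.
    """
    n_covariates = fit.model.params_.shape[0]
    if fit.n_events <= n_covariates:
        raise ValueError(
            f"PH test needs more events ({fit.n_events}) than covariates "
            f"({n_covariates})"
        )
    res = proportional_hazard_test(
        fit.model, fit.frame, time_transform=time_transform
    )
    summ = res.summary
    pvals = {str(name): float(p) for name, p in zip(summ.index, summ["p"])}
    chi2 = float(summ["test_statistic"].sum())
    df = len(pvals)
    pvals["global"] = float(stats.chi2.sf(chi2, df))
    return pvals


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio comparison of nested Cox models."""

    chi2: float
    df: int
    p: float
    ll_full: float
    ll_reduced: float


def lrt_interaction(
    data: pd.DataFrame,
    moderator: str,
    target_cause: str = "all_cause",
    *,
    fi_param: str = "per01",
    adjusters: Sequence[str] = ADJUSTERS_DEFAULT,
    adjust_age: bool = False,
) -> LRTResult:
    """Likelihood-ratio test for frailty-by-moderator effect modification.

    Fits the adjusted mortality model with and without FI-by-moderator
    product terms on the identical row set and refers twice the
    log-likelihood difference to chi-square with one degree of freedom
    per interaction term (sex: 1; education: 2 for a continuous FI).
    """
    full_frame, _, inter_terms = build_model_frame(
        data,
        fi_param=fi_param,
        adjusters=adjusters,
        adjust_age=adjust_age,
        interactions_with=moderator,
    )
    reduced_frame = full_frame.drop(columns=inter_terms)
    if not full_frame.index.equals(reduced_frame.index):
        raise ValueError("full and reduced models must use identical rows")
    ll = {}
    for name, frame in (("full", full_frame), ("reduced", reduced_frame)):
        f = frame.assign(event=_event_indicator(frame["cause"], target_cause))
        if f["event"].sum() == 0:
            raise NoEventsError(f"no events for target cause {target_cause!r}")
        cph = CoxPHFitter()
        cph.fit(f.drop(columns=["cause"]), duration_col="time", event_col="event")
        ll[name] = float(cph.log_likelihood_)
    chi2 = max(0.0, 2.0 * (ll["full"] - ll["reduced"]))
    df = len(inter_terms)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRTResult(chi2=chi2, df=df, p=p, ll_full=ll["full"], ll_reduced=ll["reduced"])
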