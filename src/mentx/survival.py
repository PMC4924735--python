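"""Progression-free-survival analysis of biomarker expression.

Cohort filtering follows the study-design rules for survival analysis:
primary, treatment-naive tumors with complete resection (Simpson grade 1-3)
and either an observed progression event or at least 36 months of follow-up.
Estimation is standard right-censored survival machinery (Kaplan-Meier,
log-rank, Cox proportional hazards via lifelines with Efron tie handling);
biomarkers enter either continuously or dichotomized at the median /
upper quartile, and the two-gene combination splits the cohort into four
groups (hazard-increasing gene by upper quartile, protective gene by
median).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test

from .io import SampleAnnotation, ValidationError

MIN_FOLLOWUP_MONTHS = 36.0
COMPLETE_RESECTION_MAX_SIMPSON = 3


def filter_survival_cohort(
    annotations: Sequence[SampleAnnotation],
    min_followup: float = MIN_FOLLOWUP_MONTHS,
) -> tuple[list[SampleAnnotation], pd.DataFrame]:
    """Apply the survival-cohort inclusion rules.

    Retained: primary, treatment-naive, Simpson 1-3, and either a recorded
    progression event or follow-up of at least ``min_followup`` months.
    Returns (eligible records, per-record exclusion log).
    """
    eligible: list[SampleAnnotation] = []
    log_rows = []
    for a in annotations:
        reasons = []
        if not a.is_primary:
            reasons.append("not a primary tumor")
        if not a.treatment_naive:
            reasons.append("prior radio-/chemotherapy")
        if a.simpson is None or a.simpson > COMPLETE_RESECTION_MAX_SIMPSON:
            reasons.append("incomplete resection (Simpson >= 4 or unknown)")
        event = bool(a.progression_event)
        if not event and (a.followup_months is None or a.followup_months < min_followup):
            reasons.append(f"censored with follow-up < {min_followup:g} months")
        if a.pfs_months is None and a.followup_months is None:
            reasons.append("no time information")
        if not reasons:
            eligible.append(a)
        log_rows.append({
            "sample_id": a.sample_id,
            "included": not reasons,
            "reasons": "; ".join(reasons),
        })
    return eligible, pd.DataFrame(log_rows)


def survival_frame(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    """Records -> (time, event, covariates) frame indexed by sample id.

    Time is PFS in months (follow-up for event-free records whose pfs field
    is missing).
    """
    rows = []
    for a in annotations:
        time = a.pfs_months if a.pfs_months is not None else a.followup_months
        if time is None:
            raise ValidationError(f"{a.sample_id}: no PFS or follow-up time")
        rows.append({
            "sample_id": a.sample_id,
            "time": float(time),
            "event": bool(a.progression_event),
            "gender": a.gender,
            "age_years": a.age_years,
            "who_grade": a.who_grade,
            "simpson": a.simpson,
        })
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Dichotomization
# ---------------------------------------------------------------------------

def dichotomize(values: pd.Series, rule: str = "median") -> tuple[pd.Series, float]:
    """Split samples into high/low at the median or the 75th percentile.

    'high' means strictly above the cut (ties at the cut go to 'low');
    quantiles use linear interpolation. Returns (labels, cut value).
    """
    v = values.astype(float)
    if v.nunique() < 2:
        raise ValidationError("all values identical: no split possible")
    if rule == "median":
        cut = float(np.quantile(v, 0.5))
    elif rule in ("upper_quartile", "q75"):
        cut = float(np.quantile(v, 0.75))
    else:
        raise ValueError("rule must be 'median' or 'upper_quartile'")
    labels = pd.Series(np.where(v > cut, "high", "low"), index=v.index, name="group")
    if labels.nunique() < 2:
        raise ValidationError(f"cut {cut} leaves a single group")
    return labels, cut


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def km_estimate(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a frame with columns time, survival (the step function evaluated
    at each distinct event/censoring time, starting from S(0)=1).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), np.asarray(events, bool))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float),
                         "survival": sf.iloc[:, 0].to_numpy(float)})


def km_median(times: Sequence[float], events: Sequence[bool]) -> float:
    kmf = KaplanMeierFitter().fit(np.asarray(times, float), np.asarray(events, bool))
    return float(kmf.median_survival_time_)


def logrank(
    times: Sequence[float], events: Sequence[bool], groups: Sequence
) -> tuple[float, float]:
    """Log-rank test; two groups or k-group multivariate form.

    Returns (chi-square statistic, p). Raises for a group with no subjects.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValidationError("log-rank needs at least two non-empty groups")
    if len(labels) == 2:
        m0, m1 = g == labels[0], g == labels[1]
        res = _ll_logrank(t[m0], t[m1], event_observed_A=e[m0], event_observed_B=e[m1])
    else:
        res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """Hazard ratios with Wald CIs plus model-level likelihood-ratio test."""

    summary: pd.DataFrame              # covariate -> hr, ci_lower, ci_upper, p_wald
    log_likelihood: float
    lr_statistic: float
    lr_p_value: float
    n: int
    n_events: int

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_lower"]), float(row["ci_upper"])


def _expand_categoricals(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Dummy-code categorical covariates against their first (reference) level."""
    X = pd.DataFrame(index=df.index)
    for cov in covariates:
        col = df[cov]
        if col.dtype.kind in "biufc" and col.nunique() > 2:
            X[cov] = col.astype(float)
        elif col.dtype.kind in "biufc":
            X[cov] = col.astype(float)
        else:
            levels = sorted(col.dropna().unique())
            ref = levels[0]
            for lev in levels[1:]:
                X[f"{cov}_{lev}_vs_{ref}"] = (col == lev).astype(float)
    return X


def cox_fit(
    df: pd.DataFrame,
    covariates: Sequence[str],
    time_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, lifelines backend).

    Categorical covariates (strings) are expanded against the alphabetically
    first level as reference; a constant covariate raises. Emits a warning
    when events < 5 x covariates (sparse-event fits are unstable).
    """
    X = _expand_categoricals(df, covariates)
    for c in X.columns:
        if X[c].nunique() <= 1:
            raise ValidationError(f"constant covariate {c!r} cannot be fitted")
    data = X.copy()
    data[time_col] = df[time_col].astype(float)
    data[event_col] = df[event_col].astype(bool)
    n_events = int(data[event_col].sum())
    if n_events < 5 * len(X.columns):
        warnings.warn(
            f"only {n_events} events for {len(X.columns)} covariates; "
            "estimates may be unstable"
        )
    cph = CoxPHFitter()
    cph.fit(data, duration_col=time_col, event_col=event_col)
    s = cph.summary
    summary = pd.DataFrame({
        "hr": s["exp(coef)"],
        "ci_lower": s["exp(coef) lower 95%"],
        "ci_upper": s["exp(coef) upper 95%"],
        "p_wald": s["p"],
        "coef": s["coef"],
        "se": s["se(coef)"],
    })
    lr = cph.log_likelihood_ratio_test()
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        lr_statistic=float(lr.test_statistic),
        lr_p_value=float(lr.p_value),
        n=len(data),
        n_events=n_events,
    )


def univariate_cox(
    df: pd.DataFrame, covariates: Sequence[str]
) -> pd.DataFrame:
    """One Cox model per covariate; rows per expanded term.

    The headline p per covariate is the model likelihood-ratio p (a
    log-rank-type statistic); Wald p per term is also reported.
    """
    rows = []
    for cov in covariates:
        fit = cox_fit(df, [cov])
        for term, r in fit.summary.iterrows():
            rows.append({
                "covariate": cov,
                "term": term,
                "hr": r["hr"],
                "ci_lower": r["ci_lower"],
                "ci_upper": r["ci_upper"],
                "p_wald": r["p_wald"],
                "p_lr": fit.lr_p_value,
            })
    return pd.DataFrame(rows)


def multivariate_covariate_set(
    univariate: pd.DataFrame, alpha: float = 0.05
) -> list[str]:
    """Covariates whose univariate model p falls below ``alpha``.

    Pure function of the univariate p-values: this is the selection rule
    'all parameters significant in univariate analysis enter the
    multivariate model'.
    """
    keep = []
    for cov, grp in univariate.groupby("covariate", sort=False):
        if (grp["p_lr"] < alpha).any():
            keep.append(cov)
    return keep


def select_genes_for_multivariate(
    gene_pvalues: dict[str, float], p_cutoff: float = 0.001, max_genes: int = 2
) -> list[str]:
    """Gene entry rule: lowest unadjusted univariate p below the cutoff.

    At most ``max_genes`` genes (default two) qualify, keeping the
    multivariate model parsimonious in a medium-sized cohort.
    """
    qualifying = sorted(
        (p, g) for g, p in gene_pvalues.items() if p < p_cutoff
    )
    return [g for _, g in qualifying[:max_genes]]


# ---------------------------------------------------------------------------
# Combined two-gene grouping
# ---------------------------------------------------------------------------

COMBINED_GROUPS = (
    "PTTG1-high/LEPR-high",
    "PTTG1-high/LEPR-low",
    "PTTG1-low/LEPR-high",
    "PTTG1-low/LEPR-low",
)


def combined_gene_groups(
    pttg1_values: pd.Series,
    lepr_values: pd.Series,
    times: pd.Series | None = None,
    events: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame, tuple[float, float] | None]:
    """Four-way grouping: hazard gene by upper quartile, protective by median.

    Returns (per-sample labels, group-size/median-PFS table, and the k-group
    log-rank (statistic, p) when survival columns are supplied).
    """
    idx = pttg1_values.index.intersection(lepr_values.index)
    p_lab, _ = dichotomize(pttg1_values.loc[idx], "upper_quartile")
    l_lab, _ = dichotomize(lepr_values.loc[idx], "median")
    labels = pd.Series(
        [f"PTTG1-{p}/LEPR-{l}" for p, l in zip(p_lab, l_lab)],
        index=idx, name="group",
    )
    rows = []
    for g in COMBINED_GROUPS:
        members = labels.index[labels == g]
        row = {"group": g, "n": len(members)}
        if times is not None and events is not None and len(members) > 0:
            row["median_pfs"] = km_median(
                times.loc[members].to_numpy(), events.loc[members].to_numpy()
            )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("group")
    test = None
    if times is not None and events is not None and labels.nunique() > 1:
        test = logrank(times.loc[idx], events.loc[idx].astype(bool), labels)
    return labels, table, test
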