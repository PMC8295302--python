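"""Survival-analysis validation of a prognosis classifier.

Kaplan-Meier curves per predicted group, the two-group log-rank test,
Harrell's concordance index of the continuous risk scores, and a Cox
proportional-hazards baseline fitted on the same features.  The event is
disease-specific death; alive / other-cause deaths are right-censored.
Estimation is delegated to lifelines; tests hold the estimators to
hand-computed toy tables and brute-force pair enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_cindex

logger = logging.getLogger(__name__)


@dataclass
class SurvivalRecords:
    """Aligned vectors of follow-up time (months) and event indicator."""

    times: np.ndarray
    events: np.ndarray  # 1 = disease death observed, 0 = censored

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if (self.times < 0).any():
            raise ValueError("negative survival time")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must align")

    def __len__(self):
        return len(self.times)


def records_from_clinical(clinical_df: pd.DataFrame, sample_ids) -> SurvivalRecords:
    sub = clinical_df.loc[list(sample_ids)]
    return SurvivalRecords(
        times=sub["survival_time_months"].to_numpy(dtype=float),
        events=(sub["event"] == "disease_death").to_numpy(dtype=int),
    )


@dataclass
class KMEstimate:
    event_times: np.ndarray   # distinct times with >= 1 observed event
    survival: np.ndarray      # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous product-limit survival at time t."""
        s = 1.0
        for time, surv in zip(self.event_times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return float(s)


def kaplan_meier(records: SurvivalRecords) -> KMEstimate:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Subjects censored at an event time remain at risk at that time
    (standard right-continuous convention).
    """
    if len(records) == 0:
        raise ValueError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(records.times, records.events)
    table = kmf.event_table
    observed = table[table["observed"] > 0]
    times = observed.index.to_numpy(dtype=float)
    surv = np.array(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in times]
    )
    return KMEstimate(
        event_times=times,
        survival=surv,
        at_risk=observed["at_risk"].to_numpy(dtype=int),
        n_events=observed["observed"].to_numpy(dtype=int),
    )


def log_rank_test(
    group1: SurvivalRecords, group2: SurvivalRecords
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p from chi2_1).

    Degenerate inputs with zero total variance (e.g. no events) give
    (0, 1) by convention.
    """
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("both groups must be non-empty")
    if group1.events.sum() + group2.events.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(
        group1.times, group2.times,
        event_observed_A=group1.events, event_observed_B=group2.events,
    )
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi2):
        return 0.0, 1.0
    return chi2, p


def concordance_index(risk_scores, records: SurvivalRecords) -> float:
    """Harrell's C: over pairs where the earlier time is an observed event,
    the fraction in which the earlier-event subject carries the higher
    risk, ties in risk counting one half."""
    risk = np.asarray(risk_scores, dtype=float)
    if len(risk) != len(records):
        raise ValueError("scores and records must align")
    t, e = records.times, records.events
    # pair (i, j) admissible iff t_i < t_j and subject i had the event
    admissible = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_adm = int(admissible.sum())
    if n_adm == 0:
        raise ValueError("no admissible pairs (no observed events)")
    higher = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    concordant = float((admissible & higher).sum())
    half = float((admissible & tied).sum())
    return (concordant + 0.5 * half) / n_adm


@dataclass
class CoxResult:
    coefficients: pd.Series
    concordance: float
    fitter: CoxPHFitter


def fit_cox_baseline(
    features: pd.DataFrame, records: SurvivalRecords
) -> CoxResult:
    """Cox proportional-hazards baseline (Breslow ties) on standardized
    features; reports coefficients and Harrell's C of the linear predictor."""
    x = features.to_numpy(dtype=float)
    if records.events.sum() < 1:
        raise ValueError("need at least one observed event")
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered) < x.shape[1]:
        raise ValueError("feature matrix is rank-deficient")
    std = x.std(axis=0)
    std[std == 0] = 1.0
    xs = pd.DataFrame(
        (x - x.mean(axis=0)) / std, columns=features.columns,
        index=features.index,
    )
    df = xs.copy()
    df["_time"] = records.times
    df["_event"] = records.events
    cph = CoxPHFitter(baseline_estimation_method="breslow")
    cph.fit(df, duration_col="_time", event_col="_event")
    risk = cph.predict_partial_hazard(xs).to_numpy()
    # undo the standardization so coefficients are per original unit
    coefs = cph.params_ / std
    return CoxResult(
        coefficients=pd.Series(coefs.to_numpy(), index=features.columns),
        concordance=concordance_index(risk, records),
        fitter=cph,
    )


@dataclass
class SurvivalReport:
    km_by_group: dict
    five_year_survival: dict
    logrank_chi2: float | None
    logrank_p: float | None
    c_index: float
    group_sizes: dict


def survival_report(
    scores,
    records: SurvivalRecords,
    threshold: float = 0.5,
    horizon_months: float = 60.0,
) -> SurvivalReport:
    """Summarise a classifier's scores against observed survival.

    Samples are split into predicted-poor (score >= threshold) and
    predicted-good groups; the report carries each group's KM estimate and
    survival at the horizon, the log-rank comparison, and Harrell's C of
    the continuous scores.
    """
    scores = np.asarray(scores, dtype=float)
    poor_mask = scores >= threshold
    groups = {}
    if poor_mask.any():
        groups["poor"] = SurvivalRecords(
            records.times[poor_mask], records.events[poor_mask]
        )
    if (~poor_mask).any():
        groups["good"] = SurvivalRecords(
            records.times[~poor_mask], records.events[~poor_mask]
        )
    km = {name: kaplan_meier(rec) for name, rec in groups.items()}
    five_year = {
        name: est.survival_at(horizon_months) for name, est in km.items()
    }
    if len(groups) == 2:
        chi2, p = log_rank_test(groups["poor"], groups["good"])
    else:
        logger.warning(
            "all samples predicted into one group; log-rank skipped"
        )
        chi2 = p = None
    return SurvivalReport(
        km_by_group=km,
        five_year_survival=five_year,
        logrank_chi2=chi2,
        logrank_p=p,
        c_index=concordance_index(scores, records),
        group_sizes={k: len(v) for k, v in groups.items()},
    )
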