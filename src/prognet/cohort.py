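"""Prognosis labeling, cohort filtering and stratified splitting.

Labels follow the 5-year disease-specific-survival convention: patients who
died of the disease within the horizon are the poor-prognosis class, patients
who died of the disease after the horizon are the good-prognosis class, and
censored patients (alive, or died of another cause) are unlabeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix, SplitSpec

logger = logging.getLogger(__name__)

DEFAULT_HORIZON_MONTHS = 60.0


def derive_labels(
    clinical: ClinicalTable, horizon_months: float = DEFAULT_HORIZON_MONTHS
) -> pd.Series:
    """Map each sample to ``poor`` / ``good`` / ``unlabeled``.

    ``disease_death`` at time <= horizon -> poor ("within" includes the
    endpoint); ``disease_death`` after the horizon -> good; anything else
    (alive, other-cause death, unknown event) is censored -> unlabeled.
    """
    times = pd.to_numeric(
        clinical.data["survival_time_months"], errors="coerce"
    )
    if (times.dropna() < 0).any():
        raise ValueError("negative survival time")
    events = clinical.data["event"]
    labels = pd.Series("unlabeled", index=clinical.data.index, dtype=object)
    died = events == "disease_death"
    labels[died & (times <= horizon_months)] = "poor"
    labels[died & (times > horizon_months)] = "good"
    return labels


@dataclass
class CohortFilterResult:
    labeled_ids: list
    unlabeled_ids: list
    exclusion_log: pd.DataFrame  # columns: sample_id, reason

    @property
    def labeled_before_clinical_filter(self) -> int:
        n_incomplete = int(
            (self.exclusion_log["reason"] == "incomplete_clinical").sum()
        )
        return len(self.labeled_ids) + n_incomplete


def filter_cohort(
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    labels: pd.Series,
    required_clinical_columns: list[str] | None = None,
) -> CohortFilterResult:
    """Apply the cohort exclusion cascade.

    Samples lacking expression data are excluded first; censored samples form
    the unlabeled set; labeled samples missing any required clinical feature
    are excluded.  Every removal is recorded with its reason so that
    ``|labeled| + |unlabeled| + |excluded| = |input|``.
    """
    if required_clinical_columns is None:
        required_clinical_columns = [
            c
            for c in clinical.data.columns
            if c not in ("survival_time_months", "event")
        ]
    have_expr = set(expression.samples)
    exclusions: list[tuple[str, str]] = []
    labeled_ids, unlabeled_ids = [], []
    for sid in clinical.samples:
        if sid not in have_expr:
            exclusions.append((sid, "no_expression"))
            continue
        if labels.get(sid, "unlabeled") == "unlabeled":
            unlabeled_ids.append(sid)
            continue
        row = clinical.data.loc[sid, required_clinical_columns]
        if row.isna().any():
            exclusions.append((sid, "incomplete_clinical"))
            continue
        labeled_ids.append(sid)
    log = pd.DataFrame(exclusions, columns=["sample_id", "reason"])
    if len(log):
        logger.info(
            "cohort filter: excluded %d samples (%s)",
            len(log),
            log["reason"].value_counts().to_dict(),
        )
    return CohortFilterResult(labeled_ids, unlabeled_ids, log)


def _round_half_even(x: float) -> int:
    return int(np.round(x))


def stratified_split(
    labels: pd.Series, test_fraction: float, seed: int
) -> SplitSpec:
    """Stratified labeled-set split into train and hold-out test.

    Per-class test counts are ``round(class_size * test_fraction)`` with ties
    to even; if the per-class sum misses the overall rounded target, the
    largest class is adjusted by +/-1.  Deterministic given the seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    labeled = labels[labels.isin(["poor", "good"])]
    counts = labeled.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 samples in each prognosis class")
    target_total = _round_half_even(len(labeled) * test_fraction)
    per_class = {
        cls: _round_half_even(n * test_fraction) for cls, n in counts.items()
    }
    largest = counts.idxmax()
    while sum(per_class.values()) != target_total:
        per_class[largest] += 1 if sum(per_class.values()) < target_total else -1
    rng = np.random.default_rng(seed)
    test_ids: list = []
    for cls, n_test in per_class.items():
        members = sorted(labeled.index[labeled == cls])
        picked = rng.choice(len(members), size=n_test, replace=False)
        test_ids.extend(members[i] for i in picked)
    test_set = set(test_ids)
    train_ids = [s for s in labeled.index if s not in test_set]
    return SplitSpec(
        train_ids=tuple(train_ids), test_ids=tuple(sorted(test_ids)), seed=seed
    )
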