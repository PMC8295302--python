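"""Core containers for the prognosis pipeline.

An :class:`ExpressionMatrix` is a genes x samples table of continuous
(log-intensity) expression values; a :class:`ClinicalTable` holds one row per
patient with immunohistochemistry biomarker statuses, clinical covariates and
disease-specific survival fields.  Interaction networks are plain
:class:`networkx.Graph` objects over gene symbols; prognosis labels are a
pandas Series mapping sample id to ``poor`` / ``good`` / ``unlabeled``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_VALUES = frozenset({"disease_death", "other_death", "alive"})
STATUS_VALUES = frozenset({"positive", "negative", "unknown"})

#: IHC biomarker status columns required by the receptor-based split criteria.
STATUS_COLUMNS = ("er_status", "pr_status", "her2_status")

#: Survival fields required to derive prognosis labels.
SURVIVAL_COLUMNS = ("survival_time_months", "event")

LABEL_VALUES = ("poor", "good", "unlabeled")


class InputFormatError(ValueError):
    """Raised when an input file violates its documented format."""


class ExpressionMatrix:
    """Genes x samples matrix of continuous expression values.

    Parameters
    ----------
    data:
        DataFrame indexed by unique gene symbols with unique sample-id
        columns; every value must be finite.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes[:5]}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        values = data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression values must all be finite")
        self.data = data.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)])

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)


class ClinicalTable:
    """Per-patient clinical covariates, biomarker statuses and survival.

    The index is the sample id.  Biomarker status columns are restricted to
    ``positive`` / ``negative`` / ``unknown``; ``event`` is one of
    ``disease_death`` / ``other_death`` / ``alive``; survival times are
    non-negative months.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise ValueError("one row per sample required")
        for col in SURVIVAL_COLUMNS:
            if col not in data.columns:
                raise ValueError(f"missing required column {col!r}")
        times = pd.to_numeric(data["survival_time_months"], errors="coerce")
        if (times.dropna() < 0).any():
            raise ValueError("survival_time_months must be >= 0")
        bad_events = set(data["event"].dropna()) - EVENT_VALUES
        if bad_events:
            raise ValueError(f"invalid event values: {sorted(bad_events)}")
        for col in STATUS_COLUMNS:
            if col in data.columns:
                bad = set(data[col].dropna()) - STATUS_VALUES
                if bad:
                    raise ValueError(f"invalid {col} values: {sorted(bad)}")
        self.data = data

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)])


@dataclass(frozen=True)
class SplitSpec:
    """A reproducible train / hold-out-test partition of the labeled set."""

    train_ids: tuple
    test_ids: tuple
    seed: int

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


@dataclass
class GeneRanking:
    """A total order over genes, rank 1 = most important.

    ``order`` lists gene symbols from best to worst (score-descending with a
    lexicographic tie-break); ``ranks`` carries the numeric rank per gene with
    tied scores receiving the average of their covered ranks.
    """

    order: list[str]
    ranks: pd.Series

    def top(self, k: int) -> list[str]:
        if k > len(self.order):
            raise ValueError(f"k={k} exceeds ranking length {len(self.order)}")
        return self.order[:k]


def rank_scores(scores: pd.Series) -> GeneRanking:
    """Turn a gene score table (higher = more important) into a ranking."""
    if scores.empty:
        raise ValueError("empty score table")
    ranks = scores.rank(ascending=False, method="average")
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return GeneRanking(order=order, ranks=ranks)
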