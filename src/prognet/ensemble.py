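"""Ensemble strategies around the core selector.

Three ways to stabilise the high-dimension / low-sample-size selection:

* **data perturbation** — run one selector on several random sample subsets
  (70% of the data, five times, by default) and *sum* the score tables;
* **function perturbation** — run the selector once per split criterion on
  the same data, convert each score table to ranks, and take the *mean
  rank* per gene;
* **hybrid** — data perturbation within each criterion, then rank-mean
  aggregation across criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    GeneRanking,
    rank_scores,
)
from .selector import (
    ALL_CRITERIA,
    SelectorParams,
    SplitCriterion,
    make_split,
    run_selector,
)

logger = logging.getLogger(__name__)

MAX_REDRAWS = 20


@dataclass
class EnsembleConfig:
    subsample_rate: float = 0.7
    n_subsamples: int = 5
    criteria: tuple = ALL_CRITERIA
    seed: int = 0
    selector_params: SelectorParams = field(default_factory=SelectorParams)

    def __post_init__(self):
        if not 0 < self.subsample_rate <= 1:
            raise ValueError("subsample_rate must be in (0, 1]")
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")


def _replicate_rng(seed: int, criterion_name: str, b: int):
    # distinct, reproducible stream per (criterion, replicate)
    entropy = [seed, sum(map(ord, criterion_name)), b]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _stratified_subsample(
    groups, samples: list, rate: float, rng
) -> list:
    """Draw floor(rate * N) sample ids, stratified by the criterion groups."""
    n_total = int(np.floor(rate * len(samples)))
    strata = [list(groups.group_a), list(groups.group_b), list(groups.excluded)]
    picked: list = []
    for stratum in strata:
        n_s = int(round(len(stratum) / len(samples) * n_total))
        n_s = min(n_s, len(stratum))
        if n_s:
            idx = rng.choice(len(stratum), size=n_s, replace=False)
            picked.extend(stratum[i] for i in sorted(idx))
    # round-off can leave us short; top up from the unpicked pool
    if len(picked) < n_total:
        pool = sorted(set(samples) - set(picked))
        idx = rng.choice(len(pool), size=n_total - len(picked), replace=False)
        picked.extend(pool[i] for i in sorted(idx))
    elif len(picked) > n_total:
        drop = rng.choice(len(picked), size=len(picked) - n_total,
                          replace=False)
        picked = [s for i, s in enumerate(picked) if i not in set(drop)]
    return picked


def data_perturbation(
    criterion: SplitCriterion,
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    network: nx.Graph,
    cfg: EnsembleConfig,
    samples: list | None = None,
) -> tuple[pd.Series, GeneRanking]:
    """Subsample-and-sum ensemble of one selector.

    Each replicate runs the bare selector on a stratified subsample; the
    final score of a gene is the *sum* of its per-replicate scores (genes
    filtered out in a replicate contribute 0 there).  With one replicate at
    rate 1.0 this reduces exactly to the bare selector.
    """
    if samples is None:
        samples = [
            s for s in expression.samples if s in set(clinical.samples)
        ]
    samples = list(samples)
    if cfg.n_subsamples == 1 and cfg.subsample_rate == 1.0:
        return run_selector(
            criterion, expression, clinical, network,
            params=cfg.selector_params, samples=samples,
        )
    groups = make_split(criterion, expression, clinical, samples=samples)
    total = pd.Series(0.0, index=expression.genes, name="score")
    for b in range(cfg.n_subsamples):
        rng = _replicate_rng(cfg.seed, criterion.name, b)
        for attempt in range(MAX_REDRAWS + 1):
            subset = _stratified_subsample(
                groups, samples, cfg.subsample_rate, rng
            )
            try:
                scores, _ = run_selector(
                    criterion, expression, clinical, network,
                    params=cfg.selector_params, samples=subset,
                )
                break
            except ValueError:
                if attempt == MAX_REDRAWS:
                    raise ValueError(
                        f"criterion {criterion.name}: replicate {b} "
                        f"infeasible after {MAX_REDRAWS} redraws"
                    )
                logger.info(
                    "criterion %s replicate %d redrawn (infeasible split)",
                    criterion.name, b,
                )
        total = total.add(scores, fill_value=0.0)
    return total, rank_scores(total)


def rank_transform(scores: pd.Series) -> pd.Series:
    """Score table -> numeric ranks, 1 = best, ties averaged."""
    if scores.empty:
        raise ValueError("empty score table")
    return scores.rank(ascending=False, method="average")


def function_perturbation(
    tables: list[pd.Series] | dict[str, pd.Series],
) -> tuple[pd.Series, GeneRanking]:
    """Rank-mean aggregation across selector variants.

    Each input score table is converted to ranks; the final score of a gene
    is its mean rank (lower = better).  Gene universes are unioned — a gene
    missing from one table gets that table's worst rank + 1.  The returned
    ranking sorts by ascending mean rank with a lexicographic tie-break.
    """
    if isinstance(tables, dict):
        tables = [tables[k] for k in tables]
    if not tables:
        raise ValueError("function perturbation needs >= 1 score table")
    universe = sorted(set().union(*[set(t.index) for t in tables]))
    rank_lists = []
    for t in tables:
        ranks = rank_transform(t)
        missing = [g for g in universe if g not in ranks.index]
        if missing:
            logger.info(
                "%d genes absent from a criterion's table assigned "
                "worst rank + 1", len(missing),
            )
        full = ranks.reindex(universe)
        full[full.isna()] = len(t) + 1
        rank_lists.append(full)
    mean_rank = pd.concat(rank_lists, axis=1).mean(axis=1)
    mean_rank.name = "mean_rank"
    # lower mean rank = better; reuse the descending ranker on the negation
    ranking = rank_scores(-mean_rank)
    return mean_rank, ranking


def hybrid_ensemble(
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    network: nx.Graph,
    cfg: EnsembleConfig,
    samples: list | None = None,
) -> tuple[pd.Series, GeneRanking]:
    """Data perturbation per criterion, then rank-mean across criteria."""
    tables = {}
    for criterion in cfg.criteria:
        scores, _ = data_perturbation(
            criterion, expression, clinical, network, cfg, samples=samples
        )
        tables[criterion.name] = scores
    return function_perturbation(tables)
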