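"""Unsupervised differential interaction-network gene scoring (PRV).

The selector never sees prognosis labels.  Instead it splits the cohort by a
prognosis-relevant criterion (receptor status, subtype, or marker-gene
expression), removes genes that do not vary between the two groups with a
one-way ANOVA filter, builds a co-expression-weighted copy of the
interaction network per group, and scores each gene by how differently it
correlates with its network partners across the two groups:

    PRV(g) = (1 / deg(g)) * sum over partners p of |w_A(g,p) - w_B(g,p)|

with ``w_X`` the within-group Pearson correlation along each retained
network edge.  Genes outside the network (or isolated after filtering)
score 0 and rank last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    GeneRanking,
    rank_scores,
)

logger = logging.getLogger(__name__)

CRITERION_NAMES = ("ER", "PR", "HER2", "TN", "HP", "MKI67", "PLAU")

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_GROUP_SIZE = 10


@dataclass(frozen=True)
class SplitCriterion:
    """A rule partitioning samples into two prognosis-distinct groups.

    ER / PR / HER2 split on the clinical IHC status (positive = group A).
    TN: group A = triple negative (ER- and PR- and HER2-).
    HP: group A = hormone-receptor positive (ER+ and PR+).
    MKI67 / PLAU: group A = expression of that gene above the cohort median
    (ties go to group B).  Samples with missing inputs are excluded.
    """

    name: str

    def __post_init__(self):
        if self.name not in CRITERION_NAMES:
            raise ValueError(
                f"unknown split criterion {self.name!r}; "
                f"expected one of {CRITERION_NAMES}"
            )

    @property
    def source(self) -> str:
        return (
            "expression_median"
            if self.name in ("MKI67", "PLAU")
            else "clinical_status"
        )


ALL_CRITERIA = tuple(SplitCriterion(n) for n in CRITERION_NAMES)


@dataclass
class GroupAssignment:
    group_a: list
    group_b: list
    excluded: list

    def __post_init__(self):
        if set(self.group_a) & set(self.group_b):
            raise ValueError("groups must be disjoint")


@dataclass
class WeightedNetwork:
    """Edge-weighted view of the interaction network for one sample group."""

    nodes: list[str]
    weights: dict[frozenset, float]

    def neighbors(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {g: [] for g in self.nodes}
        for edge in self.weights:
            a, b = tuple(edge)
            adj[a].append(b)
            adj[b].append(a)
        return adj


def _status_groups(clinical: ClinicalTable, column: str, samples):
    status = clinical.data.loc[samples, column]
    a = [s for s in samples if status[s] == "positive"]
    b = [s for s in samples if status[s] == "negative"]
    exc = [s for s in samples if status[s] not in ("positive", "negative")]
    return a, b, exc


def make_split(
    criterion: SplitCriterion,
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    samples: list | None = None,
) -> GroupAssignment:
    """Assign every sample to group A, group B, or excluded."""
    if samples is None:
        samples = [s for s in expression.samples if s in set(clinical.samples)]
    samples = list(samples)

    if criterion.source == "expression_median":
        gene = criterion.name
        if gene not in expression.data.index:
            raise ValueError(
                f"criterion {criterion.name} requires gene {gene!r} "
                "in the expression matrix"
            )
        values = expression.data.loc[gene, samples]
        med = float(values.median())
        a = [s for s in samples if values[s] > med]
        b = [s for s in samples if values[s] <= med]
        return GroupAssignment(a, b, [])

    name = criterion.name
    if name in ("ER", "PR", "HER2"):
        col = {"ER": "er_status", "PR": "pr_status", "HER2": "her2_status"}[name]
        a, b, exc = _status_groups(clinical, col, samples)
        return GroupAssignment(a, b, exc)

    status = clinical.data.loc[samples, ["er_status", "pr_status", "her2_status"]]
    known = status.isin(["positive", "negative"]).all(axis=1)
    if name == "TN":
        tn = (status == "negative").all(axis=1)
        a = [s for s in samples if known[s] and tn[s]]
        b = [s for s in samples if known[s] and not tn[s]]
    else:  # HP: hormone-receptor positive = ER+ and PR+
        hp = (status["er_status"] == "positive") & (
            status["pr_status"] == "positive"
        )
        known = status[["er_status", "pr_status"]].isin(
            ["positive", "negative"]
        ).all(axis=1)
        a = [s for s in samples if known[s] and hp[s]]
        b = [s for s in samples if known[s] and not hp[s]]
    exc = [s for s in samples if not known[s]]
    return GroupAssignment(a, b, exc)


def anova_filter(
    expression: ExpressionMatrix,
    groups: GroupAssignment,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[str], pd.Series]:
    """One-way ANOVA between the two groups; retain genes with p < alpha.

    With two groups the F statistic is the squared pooled-variance t
    statistic, so p-values match the equal-variance two-sample t-test.
    Genes constant in both groups with equal means get p = 1 (never
    retained); constant genes with different means get p = 0.
    """
    if len(groups.group_a) < 2 or len(groups.group_b) < 2:
        raise ValueError("both groups need >= 2 samples for ANOVA")
    xa = expression.data.loc[:, groups.group_a].to_numpy()
    xb = expression.data.loc[:, groups.group_b].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(pooled * (1 / na + 1 / nb))
    df = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    p = 2 * stats.t.sf(np.abs(t), df)
    zero_var = se == 0
    p[zero_var & (ma == mb)] = 1.0
    p[zero_var & (ma != mb)] = 0.0
    pvalues = pd.Series(p, index=expression.data.index, name="p_value")
    retained = [g for g in expression.genes if pvalues[g] < alpha]
    return retained, pvalues


def build_group_network(
    expression: ExpressionMatrix,
    retained: list[str],
    network: nx.Graph,
    group: list,
) -> WeightedNetwork:
    """Weight retained network edges by within-group Pearson correlation."""
    if len(group) < 3:
        raise ValueError("group must have >= 3 samples")
    retained_set = set(retained) & set(network.nodes())
    nodes = [g for g in expression.genes if g in retained_set]
    edges = [
        (a, b)
        for a, b in network.edges()
        if a in retained_set and b in retained_set
    ]
    if not edges:
        logger.warning("no network edges survive the gene filter")
        return WeightedNetwork(nodes=nodes, weights={})
    x = expression.data.loc[nodes, list(group)].to_numpy()
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    nz = norms > 0
    x[nz] = x[nz] / norms[nz, None]
    idx = {g: i for i, g in enumerate(nodes)}
    weights = {}
    n_const = 0
    for a, b in edges:
        ia, ib = idx[a], idx[b]
        if not (nz[ia] and nz[ib]):
            w = 0.0  # constant gene: correlation undefined
            n_const += 1
        else:
            w = float(np.clip(x[ia] @ x[ib], -1.0, 1.0))
        weights[frozenset((a, b))] = w
    if n_const:
        logger.info("%d edges with a constant gene weighted 0", n_const)
    return WeightedNetwork(nodes=nodes, weights=weights)


def compute_prv(
    net_a: WeightedNetwork,
    net_b: WeightedNetwork,
    normalization: str = "degree",
) -> pd.Series:
    """Per-gene differential-interaction score from two weighted networks.

    ``degree`` normalisation averages |w_A - w_B| over a gene's partners
    (scores then lie in [0, 2]); ``sum`` leaves the raw sum.
    """
    if net_a.nodes != net_b.nodes or set(net_a.weights) != set(net_b.weights):
        raise ValueError("the two group networks must share nodes and edges")
    if normalization not in ("degree", "sum"):
        raise ValueError(f"unknown normalization {normalization!r}")
    diff_sum = dict.fromkeys(net_a.nodes, 0.0)
    degree = dict.fromkeys(net_a.nodes, 0)
    for edge, wa in net_a.weights.items():
        wb = net_b.weights[edge]
        d = abs(wa - wb)
        for g in edge:
            diff_sum[g] += d
            degree[g] += 1
    scores = {}
    for g in net_a.nodes:
        if degree[g] == 0:
            scores[g] = 0.0
        elif normalization == "degree":
            scores[g] = diff_sum[g] / degree[g]
        else:
            scores[g] = diff_sum[g]
    return pd.Series(scores, name="prv")


@dataclass
class SelectorParams:
    alpha: float = DEFAULT_ALPHA
    normalization: str = "degree"
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE


def run_selector(
    criterion: SplitCriterion,
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    network: nx.Graph,
    params: SelectorParams | None = None,
    samples: list | None = None,
) -> tuple[pd.Series, GeneRanking]:
    """Full selector: split, filter, weight networks, score, rank.

    Returns a score table over *all* genes of the expression matrix (genes
    removed by the filter or absent from the network score 0) and the
    derived ranking.  ``samples`` restricts the run to the given ids — pass
    unlabeled + training samples only; hold-out test samples must stay out.
    """
    params = params or SelectorParams()
    groups = make_split(criterion, expression, clinical, samples=samples)
    if (
        len(groups.group_a) < params.min_group_size
        or len(groups.group_b) < params.min_group_size
    ):
        raise ValueError(
            f"criterion {criterion.name}: group sizes "
            f"({len(groups.group_a)}, {len(groups.group_b)}) below "
            f"min_group_size={params.min_group_size}; "
            "consider a different split criterion"
        )
    sub = expression.subset_samples(groups.group_a + groups.group_b)
    retained, _ = anova_filter(sub, groups, alpha=params.alpha)
    net_a = build_group_network(expression, retained, network, groups.group_a)
    net_b = build_group_network(expression, retained, network, groups.group_b)
    prv = compute_prv(net_a, net_b, normalization=params.normalization)
    scores = pd.Series(0.0, index=expression.genes, name="prv")
    scores.loc[prv.index] = prv
    return scores, rank_scores(scores)
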