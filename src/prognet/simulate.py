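"""Synthetic cohorts with planted differential co-expression structure.

The generator emulates the shape of a breast-cancer microarray cohort: a
genes x samples expression matrix, a clinical table with IHC biomarker
statuses, covariates and disease-specific survival, and a gene interaction
network.  Each sample carries a latent prognosis class (poor / good).  A
chosen set of *planted* genes differs between the classes in how it
co-varies with its network partners: for every network edge incident to a
planted gene the within-class correlation is ``base_rho + delta_rho/2`` in
the poor class and ``base_rho - delta_rho/2`` in the good class, realised
through a Gaussian copula over the network's edge structure (a per-class
multivariate normal whose sparse correlation matrix is projected to the
nearest positive semi-definite matrix and renormalised).

Every gene receives a class mean-shift with a random sign: background
magnitudes are U(0.5, 0.9), so mean-shifted background genes survive the
downstream variance filter just as planted genes do.  Planted genes'
magnitudes carry an additional ``planted_shift_boost * delta_rho`` — genes
whose network interactions are rewired between prognosis groups are, in
real tumours, also differentially expressed — which makes ``delta_rho`` the
single signal dial and leaves the ``delta_rho = 0`` null exactly
exchangeable between planted and background genes.  MKI67 and PLAU get
fixed positive shifts in the poor class so median-expression splits on
them align with prognosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix, GeneRanking

logger = logging.getLogger(__name__)

MARKER_GENES = ("ESR1", "PGR", "ERBB2", "MKI67", "PLAU")

# IHC-positive probability per latent class; ER/PR positivity is enriched in
# good prognosis, HER2 positivity in poor, mirroring clinical prevalence
# patterns. A small fraction of statuses is unknown.
DEFAULT_BIOMARKER_PREVALENCES = {
    "er_status": {"good": 0.78, "poor": 0.42},
    "pr_status": {"good": 0.74, "poor": 0.40},
    "her2_status": {"good": 0.14, "poor": 0.46},
}
UNKNOWN_STATUS_RATE = 0.03


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 600
    n_genes: int = 500
    network_mean_degree: float = 6.0
    n_planted: int = 20
    delta_rho: float = 0.6
    base_rho: float = 0.1
    poor_fraction: float = 0.4
    background_shift: tuple = (0.4, 0.8)
    planted_shift_boost: float = 0.6  # extra |shift| per unit delta_rho
    clinical_feature_count: int = 10
    biomarker_prevalences: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_BIOMARKER_PREVALENCES.items()
        }
    )
    survival_scale_by_class: dict = field(
        default_factory=lambda: {"poor": 40.0, "good": 150.0}
    )
    censoring_rate: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted cannot exceed n_genes")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must be in [0, 1]")
        if not 0 <= self.delta_rho <= 2:
            raise ValueError("delta_rho must be in [0, 2]")
        if not -1 < self.base_rho < 1:
            raise ValueError("base_rho must be in (-1, 1)")
        for cls in ("poor", "good"):
            rho = self.base_rho + (1 if cls == "poor" else -1) * self.delta_rho / 2
            if not -0.99 < rho < 0.99:
                raise ValueError(
                    f"base_rho +/- delta_rho/2 = {rho:.3f} for class {cls!r} "
                    "is outside the positive-definite feasible range"
                )


@dataclass
class PlantedTruth:
    """Ground truth of a simulated cohort."""

    planted_genes: set[str]
    edge_effect_by_class: dict[str, float]  # class -> correlation offset
    latent_class: pd.Series  # sample id -> poor/good


def gene_symbols(n_genes: int) -> list[str]:
    """Marker genes first, then generic symbols."""
    names = list(MARKER_GENES[:n_genes])
    names += [f"G{i:04d}" for i in range(len(names) + 1, n_genes + 1)]
    return names


def generate_network(
    n_genes: int, mean_degree: float, seed: int
) -> nx.Graph:
    """Erdos-Renyi interaction network over the cohort's gene symbols."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if mean_degree <= 0 or mean_degree >= n_genes - 1:
        raise ValueError(
            f"mean_degree={mean_degree} infeasible for {n_genes} genes"
        )
    p = mean_degree / (n_genes - 1)
    rng = np.random.default_rng(seed)
    graph = nx.gnp_random_graph(n_genes, p, seed=rng)
    mapping = dict(enumerate(gene_symbols(n_genes)))
    return nx.relabel_nodes(graph, mapping)


def _class_correlation(
    cfg: SimulationConfig,
    genes: list[str],
    network: nx.Graph,
    planted: set[str],
    cls: str,
) -> np.ndarray:
    """Sparse edge-structured correlation matrix, projected to PSD."""
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    corr = np.eye(n)
    offset = cfg.delta_rho / 2 * (1 if cls == "poor" else -1)
    for a, b in network.edges():
        if a not in idx or b not in idx:
            continue
        rho = cfg.base_rho
        if a in planted or b in planted:
            rho = cfg.base_rho + offset
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    # nearest-PSD projection: clip the spectrum, renormalise the diagonal
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < 1e-8:
        vals = np.clip(vals, 1e-8, None)
        corr = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        logger.debug(
            "correlation matrix for class %s projected to PSD "
            "(min eigenvalue clipped)", cls,
        )
    return corr


def generate_cohort(
    cfg: SimulationConfig, network: nx.Graph
) -> tuple[ExpressionMatrix, ClinicalTable, PlantedTruth]:
    """Draw one cohort under the planted-signal model (seed-deterministic)."""
    rng = np.random.default_rng(cfg.seed)
    genes = gene_symbols(cfg.n_genes)
    extra = set(network.nodes()) - set(genes)
    if extra:
        raise ValueError(f"network nodes outside gene set: {sorted(extra)[:5]}")
    samples = [f"S{i:05d}" for i in range(1, cfg.n_samples + 1)]

    candidates = [g for g in genes if g not in MARKER_GENES]
    planted = set(
        rng.choice(candidates, size=cfg.n_planted, replace=False).tolist()
    )

    latent = np.where(rng.random(cfg.n_samples) < cfg.poor_fraction,
                      "poor", "good")
    latent = pd.Series(latent, index=samples, name="latent_class")

    # class mean-shifts: random sign; planted genes get the delta_rho-coupled
    # boost on top of the background magnitude
    lo, hi = cfg.background_shift
    shift = rng.uniform(lo, hi, size=cfg.n_genes)
    gidx = {g: i for i, g in enumerate(genes)}
    for g in planted:
        shift[gidx[g]] += cfg.planted_shift_boost * cfg.delta_rho
    shift *= rng.choice([-1.0, 1.0], size=cfg.n_genes)
    if "MKI67" in gidx:
        shift[gidx["MKI67"]] = 1.0   # proliferation up in poor prognosis
    if "PLAU" in gidx:
        shift[gidx["PLAU"]] = 0.9

    expr = np.empty((cfg.n_samples, cfg.n_genes))
    for cls in ("poor", "good"):
        mask = (latent == cls).to_numpy()
        if not mask.any():
            continue
        corr = _class_correlation(cfg, genes, network, planted, cls)
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((int(mask.sum()), cfg.n_genes)) @ chol.T
        mean = shift / 2 if cls == "poor" else -shift / 2
        expr[mask] = z + mean
    expression = ExpressionMatrix(
        pd.DataFrame(expr.T, index=genes, columns=samples)
    )

    clinical = _generate_clinical(cfg, rng, latent)
    truth = PlantedTruth(
        planted_genes=planted,
        edge_effect_by_class={
            "poor": cfg.delta_rho / 2,
            "good": -cfg.delta_rho / 2,
        },
        latent_class=latent,
    )
    return expression, clinical, truth


def _generate_clinical(
    cfg: SimulationConfig, rng: np.random.Generator, latent: pd.Series
) -> ClinicalTable:
    n = len(latent)
    poor = (latent == "poor").to_numpy()
    cols: dict[str, np.ndarray | list] = {}

    for name, prev in cfg.biomarker_prevalences.items():
        p_pos = np.where(poor, prev["poor"], prev["good"])
        status = np.where(rng.random(n) < p_pos, "positive", "negative")
        unknown = rng.random(n) < UNKNOWN_STATUS_RATE
        status = np.where(unknown, "unknown", status)
        cols[name] = status.tolist()

    # tumour grade: ordinal categorical, skewed towards 3 in poor prognosis
    grade_p = np.where(poor[:, None],
                       np.array([[0.1, 0.3, 0.6]]),
                       np.array([[0.4, 0.4, 0.2]]))
    u = rng.random(n)
    grade = 1 + (u > grade_p[:, 0]).astype(int) \
              + (u > grade_p[:, :2].sum(axis=1)).astype(int)
    cols["grade"] = [f"g{g}" for g in grade]

    n_numeric = max(cfg.clinical_feature_count - 4, 0)
    n_inform = n_numeric // 2
    for i in range(n_numeric):
        if i < n_inform:
            d = rng.uniform(0.4, 0.8)
            vals = rng.standard_normal(n) + np.where(poor, d / 2, -d / 2)
        else:
            vals = rng.standard_normal(n)
        cols[f"cf{i + 1:02d}"] = vals

    scales = cfg.survival_scale_by_class
    t_event = rng.exponential(
        np.where(poor, scales["poor"], scales["good"])
    )
    censored = rng.random(n) < cfg.censoring_rate
    t_obs = np.where(censored, rng.uniform(0, 1, size=n) * t_event, t_event)
    event = np.where(
        censored,
        np.where(rng.random(n) < 0.3, "other_death", "alive"),
        "disease_death",
    )
    cols["survival_time_months"] = t_obs
    cols["event"] = event.tolist()

    df = pd.DataFrame(cols, index=latent.index)
    return ClinicalTable(df)


def truth_recall_at_k(
    ranking: GeneRanking, truth: PlantedTruth, k: int
) -> float:
    """Fraction of planted genes recovered in the top k of a ranking."""
    if k < 1:
        raise ValueError("k must be >= 1")
    top = set(ranking.top(k))
    return len(top & truth.planted_genes) / len(truth.planted_genes)


def write_truth(truth: PlantedTruth, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(truth.planted_genes):
            fh.write(g + "\n")
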