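"""Config-driven end-to-end runner for the two-stage workflow.

Stage 1 ranks genes with the bare selectors and the three ensemble
strategies, then measures selection robustness by repeated random
validation.  Stage 2 trains prognosis classifiers on the selected genes
(plus the well-established marker genes), evaluates them on the hold-out
test set in a gene / clinical / combined layout, and validates the best
combined model with survival analysis.  Feature selection and grid search
only ever see unlabeled + training samples; the hold-out test set enters at
final evaluation only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .cohort import derive_labels, filter_cohort, stratified_split
from .datatypes import ClinicalTable, ExpressionMatrix, GeneRanking
from .ensemble import (
    EnsembleConfig,
    data_perturbation,
    function_perturbation,
    hybrid_ensemble,
)
from .metrics import evaluate_accuracy, evaluate_auc
from .models import (
    DEFAULT_GRIDS,
    ModelSpec,
    grid_search_cv,
    make_bundle,
    train,
)
from .selector import ALL_CRITERIA, run_selector
from .simulate import (
    MARKER_GENES,
    SimulationConfig,
    generate_cohort,
    generate_network,
)
from .survival import records_from_clinical, survival_report
from .validation import (
    paired_onetailed_ttest,
    run_random_validation,
    summarized_area,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    output_dir: str = "prognet_run"
    seed: int = 0
    # either simulation or explicit file paths
    simulation: SimulationConfig | None = None
    expression_path: str | None = None
    clinical_path: str | None = None
    network_path: str | None = None
    network_dialect: str = "edge_list"
    test_fraction: float = 0.2
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    n_iter: int = 30
    k_max: int = 50
    validate_methods: tuple = ("hybrid", "function") + tuple(
        f"bare_{c.name}" for c in ALL_CRITERIA
    )
    top_k: int | None = None  # None -> peak of the hybrid averaged curve
    families: tuple = ("logreg", "svm", "rf", "dnn", "bimodal_dnn")
    modalities: tuple = ("gene", "clinical", "combined")
    grids: dict = field(default_factory=lambda: dict(DEFAULT_GRIDS))

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if "ensemble" in raw and raw["ensemble"] is not None:
            raw["ensemble"] = EnsembleConfig(**raw["ensemble"])
        for key in ("validate_methods", "families", "modalities"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return PipelineConfig(**raw)

    def config_hash(self) -> str:
        def default(o):
            try:
                return asdict(o)
            except TypeError:
                return repr(o)
        blob = json.dumps(asdict_safe(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def asdict_safe(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {
            k: asdict_safe(getattr(obj, k))
            for k in obj.__dataclass_fields__
        }
    if isinstance(obj, (list, tuple)):
        return [asdict_safe(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): asdict_safe(v) for k, v in obj.items()}
    return repr(obj) if not isinstance(
        obj, (int, float, str, bool, type(None))
    ) else obj


def load_or_simulate(cfg: PipelineConfig):
    """Return (expression, clinical, network, truth-or-None)."""
    if cfg.simulation is not None:
        network = generate_network(
            cfg.simulation.n_genes,
            cfg.simulation.network_mean_degree,
            cfg.simulation.seed,
        )
        expression, clinical, truth = generate_cohort(cfg.simulation, network)
        return expression, clinical, network, truth
    expression = pio.read_expression(cfg.expression_path)
    clinical = pio.read_clinical(cfg.clinical_path)
    network = pio.read_network(cfg.network_path, dialect=cfg.network_dialect)
    return expression, clinical, network, None


@dataclass
class Stage1Result:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    network: object
    truth: object
    labels: pd.Series
    split: object
    selection_samples: list
    rankings: dict[str, GeneRanking]
    validation: dict
    ttest_matrix: pd.DataFrame | None


def run_stage1(cfg: PipelineConfig, write: bool = True) -> Stage1Result:
    expression, clinical, network, truth = load_or_simulate(cfg)
    labels = derive_labels(clinical)
    filt = filter_cohort(expression, clinical, labels)
    split = stratified_split(
        labels.loc[filt.labeled_ids], cfg.test_fraction, cfg.seed
    )
    selection_samples = filt.unlabeled_ids + list(split.train_ids)

    rankings: dict[str, GeneRanking] = {}
    bare_tables = {}
    for criterion in cfg.ensemble.criteria:
        try:
            scores, ranking = run_selector(
                criterion, expression, clinical, network,
                params=cfg.ensemble.selector_params,
                samples=selection_samples,
            )
        except ValueError as exc:
            logger.warning("bare selector skipped: %s", exc)
            continue
        bare_tables[criterion.name] = scores
        rankings[f"bare_{criterion.name}"] = ranking
    data_tables = {}
    for criterion in cfg.ensemble.criteria:
        if criterion.name not in bare_tables:
            continue
        scores, ranking = data_perturbation(
            criterion, expression, clinical, network, cfg.ensemble,
            samples=selection_samples,
        )
        data_tables[criterion.name] = scores
        rankings[f"data_{criterion.name}"] = ranking
    _, rankings["function"] = function_perturbation(bare_tables)
    _, rankings["hybrid"] = function_perturbation(data_tables)

    validation = {}
    train_ids = list(split.train_ids)
    for name in cfg.validate_methods:
        if name not in rankings:
            continue
        validation[name] = run_random_validation(
            rankings[name], expression, labels, train_ids,
            n_iter=cfg.n_iter, seed=cfg.seed, k_max=cfg.k_max,
        )
    ttest = None
    if len(validation) >= 2:
        names = list(validation)
        ttest = pd.DataFrame(index=names, columns=names, dtype=float)
        for a in names:
            for b in names:
                if a == b:
                    continue
                _, p = paired_onetailed_ttest(
                    validation[a].areas, validation[b].areas
                )
                ttest.loc[a, b] = p

    result = Stage1Result(
        expression, clinical, network, truth, labels, split,
        selection_samples, rankings, validation, ttest,
    )
    if write:
        _write_stage1(cfg, result)
    return result


def _write_stage1(cfg: PipelineConfig, res: Stage1Result) -> None:
    out = Path(cfg.output_dir)
    (out / "rankings").mkdir(parents=True, exist_ok=True)
    for name, ranking in res.rankings.items():
        pio.write_ranking(ranking, out / "rankings" / f"{name}.tsv")
    if res.validation:
        areas = pd.DataFrame(
            {name: v.areas for name, v in res.validation.items()}
        )
        areas.to_csv(out / "summarized_areas.csv", index_label="iteration")
        curves = pd.DataFrame(
            {name: v.averaged_curve for name, v in res.validation.items()},
            index=pd.RangeIndex(1, cfg.k_max + 1, name="k"),
        )
        curves.to_csv(out / "averaged_curves.csv")
    if res.ttest_matrix is not None:
        res.ttest_matrix.to_csv(out / "ttest_pvalues.csv")
    manifest = {
        "stage": 1,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_train": len(res.split.train_ids),
        "n_test": len(res.split.test_ids),
        "n_unlabeled": len(res.labels) - res.labels.isin(
            ["poor", "good"]).sum().item()
        if hasattr(res.labels, "isin") else None,
        "rankings": sorted(res.rankings),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def peak_k(averaged_curve) -> int:
    """Smallest k attaining the maximum of the averaged top-k AUC curve."""
    curve = np.asarray(averaged_curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty curve")
    return int(np.argmax(curve)) + 1


def stage2_gene_features(
    expression: ExpressionMatrix, ranking: GeneRanking, k: int
) -> list[str]:
    """Marker genes first, then the top-k selected genes (deduplicated)."""
    genes = [g for g in MARKER_GENES if g in set(expression.genes)]
    for g in ranking.top(k):
        if g not in genes:
            genes.append(g)
    return genes


@dataclass
class Stage2Result:
    top_k: int
    gene_features: list[str]
    metrics: pd.DataFrame
    models: dict
    survival: object | None


def run_stage2(
    cfg: PipelineConfig,
    stage1: Stage1Result,
    ranking_name: str = "hybrid",
    write: bool = True,
) -> Stage2Result:
    ranking = stage1.rankings[ranking_name]
    if cfg.top_k is not None:
        k = cfg.top_k
    elif ranking_name in stage1.validation:
        k = peak_k(stage1.validation[ranking_name].averaged_curve)
    else:
        k = 16
    genes = stage2_gene_features(stage1.expression, ranking, k)

    train_ids = list(stage1.split.train_ids)
    test_ids = list(stage1.split.test_ids)
    rows, models = [], {}
    for modality in cfg.modalities:
        b_train = make_bundle(
            stage1.expression, stage1.clinical, stage1.labels,
            genes, train_ids, modality,
        )
        b_test = make_bundle(
            stage1.expression, stage1.clinical, stage1.labels,
            genes, test_ids, modality,
        )
        for family in cfg.families:
            if family == "bimodal_dnn" and modality != "combined":
                continue
            if family == "dnn" and modality == "combined":
                # the bimodal architecture is the combined-input DNN
                pass
            grid = cfg.grids.get(family, {})
            if grid:
                spec, _ = grid_search_cv(
                    family, grid, b_train, seed=cfg.seed
                )
            else:
                spec = ModelSpec.make(family, {}, seed=cfg.seed)
            model = train(spec, b_train)
            scores = model.predict_proba(b_test)
            rows.append({
                "modality": modality,
                "family": family,
                "accuracy": evaluate_accuracy(scores, b_test.labels),
                "auc": evaluate_auc(scores, b_test.labels),
            })
            models[(modality, family)] = model
    metrics = pd.DataFrame(rows)

    report = None
    best_key = None
    if ("combined", "bimodal_dnn") in models:
        best_key = ("combined", "bimodal_dnn")
    elif models:
        best_key = max(
            models,
            key=lambda key: metrics.set_index(["modality", "family"])
            .loc[key, "auc"],
        )
    if best_key is not None:
        model = models[best_key]
        b_test = make_bundle(
            stage1.expression, stage1.clinical, stage1.labels,
            genes, test_ids, best_key[0],
        )
        scores = model.predict_proba(b_test)
        records = records_from_clinical(stage1.clinical.data, test_ids)
        report = survival_report(scores, records)

    result = Stage2Result(k, genes, metrics, models, report)
    if write:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "stage2_metrics.csv", index=False)
        if report is not None:
            payload = {
                "five_year_survival_by_group": report.five_year_survival,
                "logrank_chi2": report.logrank_chi2,
                "logrank_p": report.logrank_p,
                "c_index": report.c_index,
                "group_sizes": report.group_sizes,
            }
            with open(out / "survival_metrics.json", "w") as fh:
                json.dump(payload, fh, indent=2)
    return result


def run_all(cfg: PipelineConfig) -> tuple[Stage1Result, Stage2Result]:
    stage1 = run_stage1(cfg)
    stage2 = run_stage2(cfg, stage1)
    return stage1, stage2
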