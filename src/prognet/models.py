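"""Stage-2 prognosis classifiers.

Five model families — logistic regression, RBF-kernel SVM, random forest,
a feed-forward DNN, and the bimodal DNN that processes gene expression and
clinical covariates in separate subnetworks before merging — trained on
gene, clinical, or combined feature bundles with stratified 4-fold
cross-validated grid search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datatypes import ClinicalTable, ExpressionMatrix
from .metrics import evaluate_auc
from .nn import BimodalMLP

logger = logging.getLogger(__name__)

FAMILIES = ("logreg", "svm", "rf", "dnn", "bimodal_dnn")
MODALITIES = ("gene", "clinical", "combined")

# hyperparameter grids searched by default (artifact defaults)
DEFAULT_GRIDS = {
    "logreg": {"C": [0.01, 0.1, 1.0, 10.0]},
    "svm": {"C": [0.1, 1.0, 10.0], "gamma_mult": [0.5, 1.0, 2.0]},
    "rf": {"n_estimators": [200, 500], "max_depth": [None, 8]},
    "dnn": {"lr": [1e-3, 1e-4], "dropout": [0.2, 0.5]},
    "bimodal_dnn": {"lr": [1e-3, 1e-4], "dropout": [0.2, 0.5]},
}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparams: tuple  # sorted (name, value) pairs
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")

    @property
    def params(self) -> dict:
        return dict(self.hyperparams)

    @staticmethod
    def make(family: str, params: dict, seed: int = 0) -> "ModelSpec":
        return ModelSpec(family, tuple(sorted(params.items(),
                                              key=lambda kv: kv[0])), seed)


@dataclass
class FeatureBundle:
    """Per-sample features for one modality (or both)."""

    modality: str
    labels: np.ndarray                       # 1 = poor prognosis
    gene: np.ndarray | None = None           # samples x genes
    clinical: np.ndarray | None = None       # samples x encoded covariates
    gene_names: list[str] = field(default_factory=list)
    clinical_names: list[str] = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        blocks = [b for b in (self.gene, self.clinical) if b is not None]
        if not blocks:
            raise ValueError("bundle has no feature block")
        n = {b.shape[0] for b in blocks} | {len(self.labels)}
        if len(n) != 1:
            raise ValueError("row counts differ across modalities/labels")
        if any(np.isnan(b).any() for b in blocks):
            raise ValueError("bundle contains missing values after encoding")

    def matrix(self) -> np.ndarray:
        """Single design matrix (gene block first for combined input)."""
        if self.modality == "gene":
            return self.gene
        if self.modality == "clinical":
            return self.clinical
        return np.hstack([self.gene, self.clinical])

    def subset(self, idx) -> "FeatureBundle":
        idx = np.asarray(idx)
        return FeatureBundle(
            modality=self.modality,
            labels=self.labels[idx],
            gene=None if self.gene is None else self.gene[idx],
            clinical=None if self.clinical is None else self.clinical[idx],
            gene_names=self.gene_names,
            clinical_names=self.clinical_names,
            sample_ids=[self.sample_ids[i] for i in idx]
            if self.sample_ids else [],
        )


def encode_clinical(
    clinical: ClinicalTable, samples: list
) -> pd.DataFrame:
    """One-hot encode categorical columns (with an explicit ``unknown``
    level), keep numeric columns as-is.  Survival fields are not features."""
    df = clinical.data.loc[list(samples)].drop(
        columns=["survival_time_months", "event"], errors="ignore"
    )
    pieces = []
    for col in df.columns:
        if pd.api.types.is_numeric_dtype(df[col]):
            pieces.append(df[[col]].astype(float).fillna(df[col].mean()))
        else:
            values = df[col].astype(object).fillna("unknown")
            cats = sorted(set(values) | {"unknown"})
            onehot = pd.DataFrame(
                {f"{col}={c}": (values == c).astype(float) for c in cats},
                index=df.index,
            )
            pieces.append(onehot)
    return pd.concat(pieces, axis=1)


def make_bundle(
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    labels: pd.Series,
    gene_list: list[str],
    sample_ids: list,
    modality: str,
) -> FeatureBundle:
    """Assemble a feature bundle for the given samples and modality."""
    y = (labels.loc[list(sample_ids)] == "poor").astype(int).to_numpy()
    gene = clin = None
    gene_names: list[str] = []
    clin_names: list[str] = []
    if modality in ("gene", "combined"):
        gene = expression.data.loc[gene_list, list(sample_ids)].to_numpy().T
        gene_names = list(gene_list)
    if modality in ("clinical", "combined"):
        enc = encode_clinical(clinical, sample_ids)
        clin = enc.to_numpy(dtype=float)
        clin_names = list(enc.columns)
    return FeatureBundle(
        modality=modality, labels=y, gene=gene, clinical=clin,
        gene_names=gene_names, clinical_names=clin_names,
        sample_ids=list(sample_ids),
    )


class _Scaler:
    """Train-only z-scoring, replayed at prediction time."""

    def fit(self, x: np.ndarray) -> "_Scaler":
        self.mean = x.mean(axis=0)
        self.std = x.std(axis=0)
        self.std[self.std == 0] = 1.0
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std


@dataclass
class TrainedModel:
    spec: ModelSpec
    modality: str
    estimator: object
    scalers: dict
    schema: dict

    def predict_proba(self, bundle: FeatureBundle) -> np.ndarray:
        _check_schema(self.schema, bundle)
        if self.spec.family == "bimodal_dnn":
            xs = [
                self.scalers["gene"].transform(bundle.gene),
                self.scalers["clinical"].transform(bundle.clinical),
            ]
            return self.estimator.predict_proba(xs)
        x = self.scalers["all"].transform(bundle.matrix())
        if self.spec.family == "dnn":
            return self.estimator.predict_proba([x])
        return self.estimator.predict_proba(x)[:, 1]


def _check_schema(schema: dict, bundle: FeatureBundle) -> None:
    got = {"gene": bundle.gene_names, "clinical": bundle.clinical_names,
           "modality": bundle.modality}
    for key in ("gene", "clinical"):
        missing = [c for c in schema[key] if c not in got[key]]
        extra = [c for c in got[key] if c not in schema[key]]
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch for {key}: "
                f"missing={missing[:5]} extra={extra[:5]}"
            )
    if schema["modality"] != bundle.modality:
        raise ValueError(
            f"modality mismatch: model is {schema['modality']!r}, "
            f"bundle is {bundle.modality!r}"
        )


def train(spec: ModelSpec, bundle: FeatureBundle) -> TrainedModel:
    """Fit one model family on a bundle (leakage-free preprocessing)."""
    if spec.family == "bimodal_dnn" and bundle.modality != "combined":
        raise ValueError("bimodal_dnn requires the combined modality")
    if len(np.unique(bundle.labels)) < 2:
        raise ValueError("training labels are constant")
    hp = spec.params
    scalers: dict = {}
    if spec.family == "bimodal_dnn":
        scalers["gene"] = _Scaler().fit(bundle.gene)
        scalers["clinical"] = _Scaler().fit(bundle.clinical)
        xg = scalers["gene"].transform(bundle.gene)
        xc = scalers["clinical"].transform(bundle.clinical)
        est = BimodalMLP(
            branch_hidden=[hp.get("gene_hidden", (64, 32)),
                           hp.get("clinical_hidden", (16, 8))],
            joint_hidden=hp.get("joint_hidden", (16,)),
            dropout=hp.get("dropout", 0.3),
            lr=hp.get("lr", 1e-3),
            seed=spec.seed,
        ).fit([xg, xc], bundle.labels)
    else:
        x = bundle.matrix()
        scalers["all"] = _Scaler().fit(x)
        xt = scalers["all"].transform(x)
        if spec.family == "logreg":
            est = LogisticRegression(
                C=hp.get("C", 1.0), max_iter=5000, class_weight="balanced"
            ).fit(xt, bundle.labels)
        elif spec.family == "svm":
            gamma = hp.get("gamma_mult", 1.0) / (
                xt.shape[1] * max(xt.var(), 1e-12)
            )
            est = SVC(
                C=hp.get("C", 1.0), gamma=gamma, probability=True,
                class_weight="balanced", random_state=spec.seed,
            ).fit(xt, bundle.labels)
        elif spec.family == "rf":
            est = RandomForestClassifier(
                n_estimators=hp.get("n_estimators", 200),
                max_depth=hp.get("max_depth", None),
                class_weight="balanced", random_state=spec.seed,
            ).fit(xt, bundle.labels)
        elif spec.family == "dnn":
            est = BimodalMLP(
                branch_hidden=[hp.get("hidden", (64, 32))],
                joint_hidden=hp.get("joint_hidden", (16,)),
                dropout=hp.get("dropout", 0.3),
                lr=hp.get("lr", 1e-3),
                seed=spec.seed,
            ).fit([xt], bundle.labels)
        else:  # pragma: no cover
            raise ValueError(spec.family)
    schema = {"gene": list(bundle.gene_names),
              "clinical": list(bundle.clinical_names),
              "modality": bundle.modality}
    return TrainedModel(spec=spec, modality=bundle.modality,
                        estimator=est, scalers=scalers, schema=schema)


def grid_points(grid: dict) -> list[dict]:
    """Expand a dict of lists into grid points in documented order."""
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in product(*grid.values())]


def grid_search_cv(
    family: str,
    grid: dict,
    bundle: FeatureBundle,
    folds: int = 4,
    seed: int = 0,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Stratified k-fold grid search scored by mean validation AUC.

    Ties are broken towards the first grid point in documented order.
    Returns the winning spec and the per-point CV table.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    points = grid_points(grid)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y = bundle.labels
    rows = []
    best_auc, best_spec = -np.inf, None
    for point in points:
        spec = ModelSpec.make(family, point, seed=seed)
        fold_aucs = []
        for tr_idx, val_idx in skf.split(np.zeros(len(y)), y):
            model = train(spec, bundle.subset(tr_idx))
            scores = model.predict_proba(bundle.subset(val_idx))
            fold_aucs.append(evaluate_auc(scores, y[val_idx]))
        mean_auc = float(np.mean(fold_aucs))
        rows.append({**point, "cv_auc": mean_auc})
        if mean_auc > best_auc:
            best_auc, best_spec = mean_auc, spec
    return best_spec, pd.DataFrame(rows)
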