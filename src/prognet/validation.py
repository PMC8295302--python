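"""Stage-1 evaluation: repeated random validation of gene rankings.

A ranking is judged by how well its top-k genes (k = 1..50) predict the
5-year prognosis label under a plain logistic regression, on repeated
stratified 3/4 : 1/4 re-splits of the training set.  The mean of the 50
per-k validation AUCs is the *summarized area* of one iteration; the
distribution of summarized areas over iterations measures how robust a
feature-selection method is.  Methods are compared with a one-tailed
paired t-test over iterations that share split seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .datatypes import ExpressionMatrix, GeneRanking
from .metrics import evaluate_auc

logger = logging.getLogger(__name__)

DEFAULT_K_MAX = 50
#: fixed L2 regularisation for the stage-1 probe classifier
LOGREG_C = 1.0


def random_split(
    train_ids: list, labels: pd.Series, seed: int,
    validation_fraction: float = 0.25,
) -> tuple[list, list]:
    """Stratified 3/4 : 1/4 split of the training ids, seed-deterministic."""
    rng = np.random.default_rng(seed)
    sub_train: list = []
    validation: list = []
    lab = labels.loc[list(train_ids)]
    for cls in sorted(lab.unique()):
        members = sorted(lab.index[lab == cls])
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has < 2 training samples")
        n_val = int(round(len(members) * validation_fraction))
        n_val = min(max(n_val, 1), len(members) - 1)
        idx = set(rng.choice(len(members), size=n_val, replace=False).tolist())
        for i, s in enumerate(members):
            (validation if i in idx else sub_train).append(s)
    return sub_train, validation


def _standardize(train: np.ndarray, other: np.ndarray):
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    std[std == 0] = 1.0
    return (train - mean) / std, (other - mean) / std


def topk_auc_curve(
    ranking: GeneRanking,
    expression: ExpressionMatrix,
    labels: pd.Series,
    sub_train: list,
    validation: list,
    k_max: int = DEFAULT_K_MAX,
) -> np.ndarray:
    """Validation AUC of logistic regression on the top-k genes, k=1..k_max.

    Features are z-scored on sub-train statistics only.
    """
    y_val = (labels.loc[validation] == "poor").astype(int).to_numpy()
    y_train = (labels.loc[sub_train] == "poor").astype(int).to_numpy()
    if len(np.unique(y_val)) < 2 or len(np.unique(y_train)) < 2:
        raise ValueError("both classes required in sub-train and validation")
    genes = ranking.top(k_max)
    x_train_full = expression.data.loc[genes, sub_train].to_numpy().T
    x_val_full = expression.data.loc[genes, validation].to_numpy().T
    curve = np.empty(k_max)
    for k in range(1, k_max + 1):
        xt, xv = _standardize(x_train_full[:, :k], x_val_full[:, :k])
        clf = LogisticRegression(C=LOGREG_C, max_iter=1000)
        clf.fit(xt, y_train)
        curve[k - 1] = evaluate_auc(clf.predict_proba(xv)[:, 1], y_val)
    return curve


def summarized_area(curve: np.ndarray) -> float:
    """Area under the top-k AUC curve, normalised by width (i.e. the mean)."""
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty curve")
    return float(curve.mean())


@dataclass
class ValidationResult:
    curves: np.ndarray          # (n_iter, k_max)
    areas: np.ndarray           # (n_iter,)
    averaged_curve: np.ndarray  # (k_max,)
    iteration_seeds: list[int]


def iteration_seed(master_seed: int, i: int) -> int:
    """Deterministic per-iteration seed shared across compared methods."""
    ss = np.random.SeedSequence([master_seed, i])
    return int(ss.generate_state(1)[0] % (2**31))


def run_random_validation(
    method,
    expression: ExpressionMatrix,
    labels: pd.Series,
    train_ids: list,
    n_iter: int = 100,
    seed: int = 0,
    k_max: int = DEFAULT_K_MAX,
    max_resamples: int = 20,
) -> ValidationResult:
    """Repeat the split-fit-score loop ``n_iter`` times.

    ``method`` is either a fixed :class:`GeneRanking` (ranked once on the
    full training data) or a callable ``sub_train_ids -> GeneRanking``
    re-ranking inside every iteration.  Iterations with a degenerate
    validation set are re-drawn with a perturbed seed.
    """
    curves = np.empty((n_iter, k_max))
    seeds = []
    for i in range(n_iter):
        it_seed = iteration_seed(seed, i)
        for retry in range(max_resamples):
            try:
                sub_train, validation = random_split(
                    train_ids, labels, it_seed + retry
                )
                ranking = method(sub_train) if callable(method) else method
                curves[i] = topk_auc_curve(
                    ranking, expression, labels, sub_train, validation,
                    k_max=k_max,
                )
                break
            except ValueError:
                if retry == max_resamples - 1:
                    raise
        seeds.append(it_seed)
    areas = curves.mean(axis=1)
    return ValidationResult(
        curves=curves,
        areas=areas,
        averaged_curve=curves.mean(axis=0),
        iteration_seeds=seeds,
    )


def paired_onetailed_ttest(areas_a, areas_b) -> tuple[float, float]:
    """One-tailed paired t-test for mean(a) > mean(b).

    Returns (t, upper-tail p).  If the paired differences have zero
    variance the p-value is 0 / 1 / 0.5 for positive / negative / zero
    mean difference.
    """
    a = np.asarray(areas_a, dtype=float)
    b = np.asarray(areas_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired samples of size >= 2")
    d = a - b
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        m = d.mean()
        return (np.inf if m > 0 else (-np.inf if m < 0 else 0.0),
                0.0 if m > 0 else (1.0 if m < 0 else 0.5))
    t = d.mean() / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    return float(t), p
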