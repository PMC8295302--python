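import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from prognet.cohort import derive_labels, filter_cohort, stratified_split
from prognet.simulate import SimulationConfig, generate_cohort, generate_network

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study conditions (600 x 500, 20 planted)."""
    cfg = SimulationConfig(seed=1)
    network = generate_network(cfg.n_genes, cfg.network_mean_degree, cfg.seed)
    expression, clinical, truth = generate_cohort(cfg, network)
    return cfg, network, expression, clinical, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 300 x 200 cohort for structural / pipeline tests."""
    cfg = SimulationConfig(n_samples=300, n_genes=200, n_planted=10, seed=3)
    network = generate_network(cfg.n_genes, cfg.network_mean_degree, cfg.seed)
    expression, clinical, truth = generate_cohort(cfg, network)
    return cfg, network, expression, clinical, truth


@pytest.fixture(scope="session")
def labeled_small_cohort(small_cohort):
    cfg, network, expression, clinical, truth = small_cohort
    labels = derive_labels(clinical)
    filt = filter_cohort(expression, clinical, labels)
    split = stratified_split(labels.loc[filt.labeled_ids], 0.2, cfg.seed)
    return {
        "cfg": cfg,
        "network": network,
        "expression": expression,
        "clinical": clinical,
        "truth": truth,
        "labels": labels,
        "filter": filt,
        "split": split,
        "selection_samples": filt.unlabeled_ids + list(split.train_ids),
    }


def make_clinical_frame(rows: dict) -> pd.DataFrame:
    """Helper: build a clinical DataFrame from {sample: {col: val}}."""
    return pd.DataFrame.from_dict(rows, orient="index")
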