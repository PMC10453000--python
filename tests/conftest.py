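import numpy as np
import pandas as pd
import pytest

from grnpipe.pipeline import RunConfig, compute_pipeline
from grnpipe.preprocess import normalize_total
from grnpipe.synthetic import SimulationConfig, generate_gold_standard, simulate_corpus


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Default-shaped corpus, small enough for fast tests."""
    return SimulationConfig(
        n_classes=3,
        n_tfs_per_class=2,
        targets_per_tf=5,
        n_background_genes=150,
        samples_per_class=20,
        hub_effect=4.0,
        noise_sd=0.5,
        decoy_pairs=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_corpus(small_config):
    gold, truth = generate_gold_standard(small_config)
    table, expr = simulate_corpus(small_config, truth)
    norm = normalize_total(expr)
    labels = table.set_index("sample_id")["description"]
    return {
        "config": small_config,
        "gold": gold,
        "truth": truth,
        "table": table,
        "expr": expr,
        "norm": norm,
        "labels": labels,
    }


@pytest.fixture(scope="session")
def small_run_config(small_config) -> RunConfig:
    return RunConfig(
        seed=7,
        simulation={
            "n_classes": small_config.n_classes,
            "n_tfs_per_class": small_config.n_tfs_per_class,
            "targets_per_tf": small_config.targets_per_tf,
            "n_background_genes": small_config.n_background_genes,
            "samples_per_class": small_config.samples_per_class,
            "decoy_pairs": small_config.decoy_pairs,
            "seed": small_config.seed,
        },
        n_trees=200,
        n_boot=50,
        top_k=30,
    )


@pytest.fixture(scope="session")
def pipeline_result(small_run_config):
    """One full pipeline run on the small corpus, shared across tests."""
    return compute_pipeline(small_run_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_survival(rng, n=40, censor=0.3):
    """Small random survival instance with continuous (tie-free) times."""
    time = rng.exponential(10.0, size=n)
    event = (rng.random(n) > censor).astype(int)
    group = rng.random(n) < 0.5
    if event.sum() == 0:
        event[0] = 1
    if group.all() or not group.any():
        group[0] = ~group[0]
    return time, event, group
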