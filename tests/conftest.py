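import numpy as np
import pandas as pd
import pytest

from ksnet import synthetic_data as sd
from ksnet.feature_engine import DEFAULT_REGISTRY, assemble_features
from ksnet.types import KSPair


@pytest.fixture(scope="session")
def small_world():
    """A compact world shared by read-only tests."""
    return sd.generate_world(
        n_kinases=8, n_sites=300, n_true_pairs=120, signal_strength=0.9, seed=3
    )


@pytest.fixture(scope="session")
def small_world_features(small_world):
    w = small_world
    pairs = [KSPair(k, s) for k, s in w.universe()]
    table, rejects = assemble_features(
        pairs,
        w.kinase_map(),
        w.site_map(),
        w.pssms,
        {"expression": w.expression, "proteomics": w.proteomics},
        DEFAULT_REGISTRY,
    )
    assert len(rejects) == 0
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_network_edges(rng, n_kinases=10, n_sites=60, n_edges=300):
    """Random kinase->site edge records with canonical site ids."""
    if n_edges > n_kinases * n_sites:
        raise ValueError("requested more edges than distinct pairs")
    kin = [f"K{i:02d}" for i in range(n_kinases)]
    sites = [
        f"P{i // 3:03d}_{rng.choice(['S', 'T', 'Y'])}{i + 1}" for i in range(n_sites)
    ]
    seen = set()
    records = []
    while len(records) < n_edges:
        k = kin[int(rng.integers(n_kinases))]
        s = sites[int(rng.integers(n_sites))]
        if (k, s) in seen:
            continue
        seen.add((k, s))
        records.append((k, s, float(rng.random())))
    return records


@pytest.fixture(scope="session")
def small_world_model(small_world, small_world_features):
    """A small trained ensemble shared by downstream tests."""
    from ksnet import training_engine as te
    from ksnet.types import Label

    w = small_world
    cfg = te.TrainingConfig(
        seed=11, n_runs=3, k_folds=3, neg_ratio_final=10,
        grid={"max_depth": [20], "min_samples_split": [10],
              "n_estimators": [100]},
    )
    positives = [KSPair(k, s, Label.POSITIVE) for k, s in sorted(w.truth_keys)]
    model = te.train_ensemble(small_world_features, positives, w.universe(), cfg)
    return model


@pytest.fixture(scope="session")
def small_world_network(small_world, small_world_features, small_world_model):
    from ksnet.training_engine import predict_network

    net, skipped = predict_network(
        small_world_model, small_world_features, small_world.universe()
    )
    assert len(skipped) == 0
    return net
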