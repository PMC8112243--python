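import numpy as np
import pandas as pd
import pytest

from hervlink.counts import CountMatrix
from hervlink.simulate import SimulationConfig, simulate_study


def make_count_matrix(counts, feature_ids=None, conditions=None, dataset="d1"):
    """Small CountMatrix from a 2D array-like."""
    counts = np.asarray(counts)
    n_feat, n_samp = counts.shape
    feature_ids = feature_ids or [f"F{i}" for i in range(n_feat)]
    sample_ids = [f"s{i}" for i in range(n_samp)]
    conditions = conditions or ["case"] * (n_samp // 2) + ["control"] * (n_samp - n_samp // 2)
    meta = pd.DataFrame({"condition": conditions, "dataset": dataset}, index=sample_ids)
    return CountMatrix(pd.DataFrame(counts, index=feature_ids, columns=sample_ids), meta)


@pytest.fixture(scope="session")
def small_study():
    """A compact two-dataset synthetic study reused across tests."""
    cfg = SimulationConfig(
        n_genes=500,
        n_hervs=150,
        set_size_range=(10, 20),
        n_enriched_sets=3,
        seed=20210427,
    )
    return simulate_study(cfg)


def nb_draw(rng, mean, dispersion):
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))
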