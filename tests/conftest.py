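import numpy as np
import pandas as pd
import pytest

from cdscore import synthgen as sg


@pytest.fixture(scope="session")
def bulk_cohort():
    """Default synthetic bulk cohort (6 samples/subtype, planted lfc 6)."""
    cfg = sg.SimConfig(seed=11)
    peak_counts, expr_counts, ann, truth = sg.simulate_bulk_cohort(cfg)
    return cfg, peak_counts, expr_counts, ann, truth


@pytest.fixture(scope="session")
def fragment_data():
    cfg = sg.SimConfig(seed=21)
    frags, bins, peaks, truth = sg.simulate_fragments(cfg)
    return cfg, frags, bins, peaks, truth


@pytest.fixture(scope="session")
def cell_data():
    cfg = sg.SimConfig(seed=31, n_cells_per_type=100)
    cells, truth = sg.simulate_single_cells(cfg)
    return cfg, cells, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def small_counts(rng, n_feat=200, n_samples=8, mean=30.0):
    """Plain NB null count matrix for unit tests."""
    mu = np.exp(rng.normal(np.log(mean), 0.5, n_feat))
    n = 20.0
    counts = rng.negative_binomial(n, n / (n + mu[:, None]),
                                   size=(n_feat, n_samples))
    return pd.DataFrame(counts, index=[f"f{i:03d}" for i in range(n_feat)],
                        columns=[f"s{i}" for i in range(n_samples)])
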