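import logging

import numpy as np
import pandas as pd
import pytest

from cidmem import SimulationConfig
from cidmem.preprocess import classify_chambers
from cidmem.simulate import simulate_all

logging.getLogger("cidmem").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size simulated experiment under the default study conditions."""
    return simulate_all(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_classified(default_bundle):
    classified, report = classify_chambers(default_bundle.manifest)
    return classified, report


@pytest.fixture(scope="session")
def small_config():
    """Reduced problem size for fast pipeline-level tests."""
    return SimulationConfig(
        seed=5, n_genes=400, module_sizes=[8, 6, 5, 5],
        n_lr_pairs_coordinated=4, n_lr_pairs_null=10, n_de_genes=10,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_all(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def pearson_scalar(x, y):
    """Textbook Pearson correlation, written out sum-by-sum as an oracle."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    if dx == 0 or dy == 0:
        return float("nan")
    return num / (dx * dy)


@pytest.fixture()
def pearson_oracle():
    return pearson_scalar


def random_expression(rng, n_genes=15, n_cells=12, sparsity=0.4, scale=20.0):
    vals = rng.gamma(1.0, scale, size=(n_genes, n_cells))
    vals[rng.random(vals.shape) < sparsity] = 0.0
    return pd.DataFrame(
        vals,
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"C{j:03d}" for j in range(n_cells)],
    )


@pytest.fixture()
def make_expression(rng):
    def _make(**kw):
        return random_expression(rng, **kw)
    return _make
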