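import numpy as np
import pandas as pd
import pytest

from favsdm.pipeline import PredictorTable
from favsdm.synthetic import gen_grid, gen_spatial_field


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_table():
    """A 20x20 landscape with two orthogonal-ish covariates and a response."""
    grid = gen_grid(20, 20)
    data = grid.copy()
    data["clim"] = gen_spatial_field(grid, radius=0.1, variance=1.0, seed=11)
    data["topo"] = gen_spatial_field(grid, radius=0.1, variance=1.0, seed=12)
    rng = np.random.default_rng(7)
    from scipy.special import expit

    probs = expit(-1.0 + 1.2 * data["clim"].to_numpy())
    data["presence"] = (rng.random(len(data)) < probs).astype(int)
    return PredictorTable(data=data, sets={"clim": "climate", "topo": "topography"})


def simulate_logistic(rng, n, beta0, beta1):
    """Independent scalar-covariate logistic draw (test oracle generator)."""
    from scipy.special import expit

    x = rng.standard_normal(n)
    y = (rng.random(n) < expit(beta0 + beta1 * x)).astype(int)
    return pd.DataFrame({"(Intercept)": np.ones(n), "x": x}), y
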