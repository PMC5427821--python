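import numpy as np
import pandas as pd
import pytest

import mrsurv


@pytest.fixture(scope="session")
def default_table():
    """One default three-cohort dataset shared across read-only tests."""
    return mrsurv.simulate_multi_cohort(mrsurv.default_config(seed=20170303))


@pytest.fixture(scope="session")
def default_grs(default_table):
    return mrsurv.build_grs(default_table)


@pytest.fixture()
def small_cox_data():
    """Hand-built n=6 survival dataset with a tie, for oracle comparisons."""
    return pd.DataFrame({
        "follow_up": [1.0, 2.0, 2.0, 3.0, 4.0, 5.0],
        "event": [1, 1, 1, 0, 1, 0],
        "x": [0.5, -1.0, 1.5, 0.0, 2.0, -0.5],
    })


def make_survival_frame(rng, n=300, beta=0.4, rate=0.25, quadratic=0.0):
    """Exponential survival with a (possibly curved) covariate effect."""
    z = rng.standard_normal(n)
    lam = rate * np.exp(beta * z + quadratic * z**2)
    t = rng.exponential(1.0 / lam)
    c = rng.uniform(0.5, 1.5, n)
    return pd.DataFrame({"follow_up": np.minimum(t, c),
                         "event": (t <= c).astype(int), "z": z})
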