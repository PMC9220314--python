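import numpy as np
import pandas as pd
import pytest

from soilmultifun import FunctionMatrix, OTUTable, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-configuration simulated study (seed 1), shared read-only."""
    return simulate_dataset(seed=1)


@pytest.fixture()
def small_fm():
    return FunctionMatrix(
        pd.DataFrame(
            {"bG": [1.0, 2.0, 3.0], "ALP": [10.0, 20.0, 30.0]},
            index=["p1", "p2", "p3"],
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_function_matrix(rng, n_plots=30, n_funs=10, positive=True):
    vals = rng.normal(5.0 if positive else 0.0, 1.0, size=(n_plots, n_funs))
    if positive:
        vals = np.abs(vals) + 0.1
    return FunctionMatrix(
        pd.DataFrame(
            vals,
            index=[f"p{i}" for i in range(n_plots)],
            columns=[f"F{j}" for j in range(n_funs)],
        )
    )


def random_otu_table(rng, n_samples=10, n_otus=50, depth=10_000, domain="bacteria"):
    base = rng.lognormal(0, 2.0, n_otus)
    base /= base.sum()
    counts = np.vstack([rng.multinomial(depth, base) for _ in range(n_samples)])
    keep = counts.sum(axis=0) > 0
    return OTUTable(
        pd.DataFrame(
            counts[:, keep],
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"OTU{j}" for j in np.flatnonzero(keep)],
        ),
        domain=domain,
    )
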