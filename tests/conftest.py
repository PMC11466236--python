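import numpy as np
import pandas as pd
import pytest

import clpnet as c


@pytest.fixture(scope="session")
def catalog():
    return c.default_catalog()


@pytest.fixture(scope="session")
def catalog6():
    """Small 6-node catalog (2 per community) for fast estimator tests."""
    return c.SymptomCatalog.from_records(
        [
            {"node_id": "N1", "community": "NSSI"},
            {"node_id": "N2", "community": "NSSI"},
            {"node_id": "D1", "community": "DEP"},
            {"node_id": "D2", "community": "DEP"},
            {"node_id": "A1", "community": "ANX"},
            {"node_id": "A2", "community": "ANX"},
        ]
    )


def make_panel(catalog, n=20, seed=0, incomplete_rows=()):
    """Random valid panel; listed rows get one missing wave-2 value."""
    rng = np.random.default_rng(seed)
    p = len(catalog)
    t1 = pd.DataFrame(
        rng.integers(0, 5, size=(n, p)).astype(float), columns=catalog.node_ids
    )
    t2 = pd.DataFrame(
        rng.integers(0, 5, size=(n, p)).astype(float), columns=catalog.node_ids
    )
    incomplete = np.zeros(n, dtype=bool)
    for r in incomplete_rows:
        t2.iloc[r, 0] = np.nan
        incomplete[r] = True
    return c.PanelDataset(
        subject_ids=[f"S{i}" for i in range(n)],
        gender=rng.integers(0, 2, size=n),
        t1=t1,
        t2=t2,
        catalog=catalog,
        incomplete=incomplete,
    )


@pytest.fixture
def panel_factory(catalog):
    def build(n=20, seed=0, incomplete_rows=()):
        return make_panel(catalog, n=n, seed=seed, incomplete_rows=incomplete_rows)

    return build


def make_network(catalog, W, n_subjects=100):
    """Wrap a weight matrix as a CrossLaggedNetwork for metric tests."""
    p = len(catalog)
    return c.CrossLaggedNetwork(
        W=np.asarray(W, dtype=float),
        covariate_coefs=pd.DataFrame(index=catalog.node_ids),
        intercepts=np.zeros(p),
        lambda_selected=np.zeros(p),
        config=c.EstimationConfig(),
        catalog=catalog,
        n_subjects=n_subjects,
    )


@pytest.fixture
def network_factory():
    return make_network


@pytest.fixture(scope="session")
def sparse_truth6():
    """6-node sparse linear ground truth used by estimator/bootstrap tests."""
    B = np.eye(6) * 0.3
    B[0, 1] = 0.4
    B[2, 3] = -0.35
    B[4, 5] = 0.25
    corr = np.full((6, 6), 0.3)
    np.fill_diagonal(corr, 1.0)
    return B, corr
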