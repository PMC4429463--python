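"""Shared fixtures: small hand-built datasets and simulation designs."""

import numpy as np
import pandas as pd
import pytest

import parfrail as pf
from parfrail.simulate import CovariateDesign, SimulationDesign

TOY_SCHEMA = {"group": ["a", "b"]}

TOY_CSV = """cluster,time,event,group
k1,5,1,a
k1,8,0,b
k2,3,1,a
k2,12,1,b
"""


@pytest.fixture
def toy_ds():
    return pf.load_dataset(TOY_CSV, TOY_SCHEMA)


@pytest.fixture
def sized_ds():
    """Cluster sizes {1, 2, 3, 1, 4}: exercises the singleton filter."""
    rows = []
    sizes = {"c1": 1, "c2": 2, "c3": 3, "c4": 1, "c5": 4}
    i = 0
    for cid, size in sizes.items():
        for _ in range(size):
            rows.append({"cluster": cid, "time": 2.0 + i, "event": i % 2, "group": "a"})
            i += 1
    df = pd.DataFrame(rows)
    return pf.load_dataset(df, TOY_SCHEMA)


def two_covariate_design(
    theta=0.3, rho=3.0, frailty_family="invgauss", n_clusters=150, size=5,
    beta=(0.2, -0.1), dropout=0.0105,
):
    """Log-logistic AFT truth with two binary covariates (recovery studies)."""
    return SimulationDesign(
        n_clusters=n_clusters,
        fixed_cluster_size=size,
        baseline=pf.BaselineSpec("loglogistic", lam=12.0**-rho, rho=rho),
        frailty=None if theta == 0 else pf.FrailtySpec(frailty_family, theta),
        covariates={
            "a": CovariateDesign(("no", "yes"), (0.5, 0.5), (beta[0],)),
            "b": CovariateDesign(("no", "yes"), (0.5, 0.5), (beta[1],)),
        },
        formulation="AFT",
        admin_horizon=63.0,
        dropout_rate=dropout,
    )


@pytest.fixture(scope="session")
def recovery_ds():
    """One dataset from the two-covariate log-logistic/inv-Gaussian truth."""
    ds, truth = pf.simulate_dataset(two_covariate_design(), seed=42)
    return ds, truth


@pytest.fixture(scope="session")
def recovery_fit(recovery_ds):
    ds, _ = recovery_ds
    return pf.fit(pf.ModelSpec("loglogistic", "invgauss", ("a", "b")), ds)


@pytest.fixture(scope="session")
def sam_ds():
    """One singleton-filtered SAM-shaped synthetic cohort."""
    ds, truth = pf.simulate_dataset(pf.sam_like_design(), seed=11)
    ds, _ = pf.filter_singleton_clusters(ds)
    return ds, truth
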