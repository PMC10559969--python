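import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_pedigree_frame():
    """Five cows under two sires and two MGS; one sire has a single daughter."""
    return pd.DataFrame(
        {
            "animal_id": ["c1", "c2", "c3", "c4", "c5"],
            "sire_id": ["s1", "s1", "s1", "s2", "s1"],
            "mgs_id": ["m1", "m2", "m1", "m2", "m2"],
        }
    )


@pytest.fixture(scope="session")
def small_herd():
    """A small but complete synthetic herd shared across tests."""
    from herdhealth.simulate import SimulationConfig, simulate_herd

    config = SimulationConfig(
        herd_sizes=[80, 70, 90, 60],
        n_sires=30,
        n_mgs=50,
        seed=11,
    )
    return simulate_herd(config)


def direct_minus2_restricted_ll(y, X, K, s2a, s2e):
    """Independent restricted-likelihood evaluation from the V-matrix form.

    -2 logL_R = log|V| + log|X' V^-1 X| + y' P y + (n - p) log 2pi with
    V = s2a K + s2e I and P the REML projection.  Deliberately written from
    the textbook definition (dense V, explicit projections) so it shares no
    code with the package's rotated or MME evaluation routes.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    V = s2a * np.asarray(K) + s2e * np.eye(n)
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return np.inf
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign2, logdetX = np.linalg.slogdet(XtViX)
    if sign2 <= 0:
        return np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return (
        logdetV
        + logdetX
        + float(r @ Vi @ y)
        + (n - X.shape[1]) * np.log(2 * np.pi)
    )
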