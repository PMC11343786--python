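import logging

import numpy as np
import pandas as pd
import pytest

from gdmclust.preprocessing import standardize_apply, standardize_fit
from gdmclust.synthetic import default_config, generate_cohort

# quantile-fit fallback warnings are expected noise in tests
logging.getLogger("gdmclust.synthetic").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """Reference-calibrated synthetic training cohort (n=1154, seed 0)."""
    return generate_cohort(default_config(n=1154, seed=0))


@pytest.fixture(scope="session")
def default_cohort_z(default_cohort):
    """Standardised matrix + scaler for the default cohort."""
    scaler = standardize_fit(default_cohort, "full5")
    Z = standardize_apply(default_cohort, scaler)
    return Z, scaler


def make_blobs(
    n_per: int = 60,
    k: int = 3,
    p: int = 2,
    separation: float = 10.0,
    seed: int = 0,
    spread: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Well-separated spherical Gaussian blobs with true labels 1..k."""
    rng = np.random.default_rng(seed)
    # axis-aligned centers: pairwise distances are always >= separation
    centers = np.zeros((k, p))
    for i in range(k):
        centers[i, i % p] = separation * (1 + i)
    X = np.vstack([rng.normal(c, spread, size=(n_per, p)) for c in centers])
    labels = np.repeat(np.arange(1, k + 1), n_per)
    perm = rng.permutation(len(X))
    return X[perm], labels[perm]
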