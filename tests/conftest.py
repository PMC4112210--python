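import numpy as np
import pytest

import gblupgwas as g
from gblupgwas.pipeline import run_scan


@pytest.fixture(scope="session")
def sim300():
    """Default-scale synthetic F2 cross (2 chromosomes x 400 markers)."""
    return g.simulate(seed=7)


@pytest.fixture(scope="session")
def pipe300(sim300):
    """Full scan pipeline products on the default simulated dataset."""
    return run_scan(sim300.geno, sim300.samples, sim300.phenotypes)


@pytest.fixture(scope="session")
def toy_mixed():
    """Small dense mixed-model problem with a full-rank GRM.

    Built from more markers than animals so G is positive definite and the
    Cholesky/MME routes are well defined.
    """
    rng = np.random.default_rng(42)
    n, m = 25, 80
    M = rng.binomial(2, rng.uniform(0.2, 0.8, size=m), size=(n, m)).astype(float)
    p = M.mean(axis=0) / 2
    keep = (p > 0.05) & (p < 0.95)
    M, p = M[:, keep], p[keep]
    # shift p off the in-sample means: exact centring would make G singular
    p2 = np.clip(p + 0.01, 0.02, 0.98)
    Z = g.standardize(M, p2)
    G = g.compute_grm(Z)
    u = rng.normal(0, 1.0, size=Z.n_markers)
    y = 3.0 + Z.Z @ u * 3.0 + rng.normal(0, 1.0, size=n)
    X = np.column_stack([np.ones(n), rng.integers(0, 2, size=n)])
    data = g.DesignData(y=y, X=X)
    return {"M": M, "p": p2, "Z": Z, "G": G, "data": data, "rng_seed": 42}


@pytest.fixture(scope="session")
def toy_fit(toy_mixed):
    return g.reml_fit(toy_mixed["data"], toy_mixed["G"])
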