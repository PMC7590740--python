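import itertools

import numpy as np
import pytest

import flowot as fo


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, d, scale=1.0):
    q, _ = np.linalg.qr(rng.normal(size=(d, d)))
    eigs = rng.uniform(0.5, 2.0, size=d) * scale
    return (q * eigs) @ q.T


def random_component(rng, d, spread=5.0, weight=1.0, label=None):
    return fo.GaussianComponent(
        mean=rng.normal(scale=spread, size=d),
        cov=random_spd(rng, d),
        weight=weight,
        label=label,
    )


def random_mixture(rng, d, k, sample_id=""):
    w = rng.dirichlet(np.ones(k) * 5)
    comps = [random_component(rng, d, weight=wi) for wi in w]
    return fo.MixtureClustering(components=comps, id=sample_id)


def brute_force_ot(p, q, C):
    """Minimum-cost transportation by enumerating basic feasible solutions.

    Every vertex of the transportation polytope is supported on a set of
    ki + kj - 1 cells whose bipartite graph is a spanning forest; enumerating
    all cell subsets of that size, solving the marginal equations and keeping
    the feasible ones visits every vertex.  Intended for ki, kj <= 3.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    C = np.asarray(C, float)
    ki, kj = C.shape
    cells = list(itertools.product(range(ki), range(kj)))
    m = ki + kj - 1
    best_cost = np.inf
    best_plan = None
    for support in itertools.combinations(cells, m):
        A = np.zeros((ki + kj, m))
        for col, (i, j) in enumerate(support):
            A[i, col] = 1.0
            A[ki + j, col] = 1.0
        b = np.concatenate([p, q])
        x, residuals, rank, _ = np.linalg.lstsq(A, b, rcond=None)
        if np.linalg.norm(A @ x - b) > 1e-9 or np.any(x < -1e-10):
            continue
        plan = np.zeros((ki, kj))
        for col, (i, j) in enumerate(support):
            plan[i, j] += x[col]
        cost = float((plan * C).sum())
        if cost < best_cost - 1e-15:
            best_cost = cost
            best_plan = plan
    assert best_plan is not None, "no feasible vertex found"
    return best_cost, best_plan


@pytest.fixture(scope="session")
def synthetic_db():
    """Default study conditions: 3 groups x 5 cytometries, 4 cell types, 2-D."""
    config = fo.SynthConfig(seed=20240)
    db, membership, params = fo.generate_database(config)
    return db, membership, params
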