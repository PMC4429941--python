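"""Shared fixtures: small random model instances built per test."""

import numpy as np
import pytest

from purist.data import CpeState, PpeState, ThetaMatrix


def random_instance(rng, G=50, N=4, R=3, depth=10_000):
    """A random feasible model instance (counts, panel, CPE/PPE states)."""
    B = rng.dirichlet(np.full(G, 0.8), size=R).T
    B = np.maximum(B, 1e-12)
    B /= B.sum(axis=0, keepdims=True)
    m = np.maximum(rng.dirichlet(np.full(G, 0.8)), 1e-12)
    m /= m.sum()
    theta = rng.dirichlet(np.ones(R + 1), size=N)
    nu = 1.0 + rng.uniform(0.1, 3.0, R + 1)
    omega = rng.dirichlet(np.ones(R))
    X = np.column_stack(
        [rng.multinomial(depth, rng.dirichlet(np.full(G, 0.9))) for _ in range(N)]
    )
    cpe = CpeState(
        theta=ThetaMatrix(theta), m=m, nu=nu, omega=omega,
        kappa_prime=float(rng.uniform(50, 500)),
    )
    C = np.column_stack([rng.dirichlet(5000 * m) for _ in range(N)])
    C = np.maximum(C, 1e-15)
    C /= C.sum(axis=0, keepdims=True)
    ppe = PpeState(
        cancer_profiles=C, kappa_n=rng.uniform(100, 500, N),
        theta=ThetaMatrix(theta), nu=nu, m=m, omega=omega,
        kappa_prime=cpe.kappa_prime,
    )
    return X, B, cpe, ppe


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_instance(rng):
    return random_instance(rng)
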