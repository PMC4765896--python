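"""Shared fixtures and independent numerical oracles.

The root oracle here deliberately avoids the closed-form quadratic: it
locates zeros of the per-capita rate by bracketing around its single
interior extremum (the per-capita curve of this model is increasing
then decreasing, so at most one root lies on each side) and refining
with Brent's method. It is the reference the closed-form equilibria are
checked against.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq, minimize_scalar

from hive_allee import SocialParams, fixtures, per_capita_rate


@pytest.fixture(scope="session")
def fx() -> dict[str, SocialParams]:
    return fixtures()


@pytest.fixture(scope="session")
def case2(fx) -> SocialParams:
    return fx["case2_default"]


def oracle_positive_roots(p: SocialParams) -> list[float]:
    """Positive equilibria by sign-change bracketing of the per-capita rate.

    Any positive equilibrium satisfies per_capita_rate = 0. For N above
    lam/mu the net rate is strictly negative (recruitment < lam < mu*N),
    so all roots lie in (0, lam/mu + theta + beta).
    """
    n_max = p.lam / p.mu + p.theta + p.beta
    pc = lambda n: per_capita_rate(n, p)
    # the per-capita curve has at most one interior extremum (max if the
    # mortality term dominates at the origin, min otherwise); locate it
    # from both directions and bracket sign changes between breakpoints
    breakpoints = {0.0, n_max}
    for objective in (lambda n: -pc(n), pc):
        res = minimize_scalar(
            objective, bounds=(0.0, n_max), method="bounded",
            options={"xatol": 1e-12 * n_max},
        )
        breakpoints.add(float(res.x))
    pts = sorted(breakpoints)
    roots = []
    for a, b in zip(pts, pts[1:]):
        if pc(a) * pc(b) < 0.0:
            roots.append(brentq(pc, a, b, xtol=1e-14 * n_max, rtol=8.9e-16))
    return sorted(r for r in roots if r > 0.0)


def random_param_sets(n_sets: int, seed: int, decades: float = 4.0):
    """Log-uniform parameter sets spanning ``decades`` per parameter,
    centred on the default strong-Allee fixture."""
    rng = np.random.default_rng(seed)
    base = fixtures()["case2_default"].as_dict()
    half = decades / 2.0
    sets = []
    for _ in range(n_sets):
        sets.append(SocialParams(**{
            k: v * 10.0 ** rng.uniform(-half, half) for k, v in base.items()
        }))
    return sets
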