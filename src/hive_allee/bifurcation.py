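"""Parameter sweeps, equilibrium branch tracking, and fold location.

The social hive model loses its viable state through a saddle-node
(fold) bifurcation: as a parameter degrades, the unstable critical size
rises, the stable upper size falls, and at the fold the two merge at
``-b/(2a)`` and vanish — beyond it every hive collapses regardless of
size. The fold is located on the quadratic discriminant ``b^2 - 4ac``
(a polynomial in each parameter, free of the singularities the ratio
form of the collapse index has at ``c = 0``); the index's equality with
1 at the fold is then verified post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .equilibria import (
    Case,
    classify_case,
    discriminant_quantity,
    quadratic_coefficients,
    solve_equilibria,
)
from .model_core import SocialParams

__all__ = ["BifurcationDiagram", "FoldPoint", "sweep", "find_fold", "viability_region"]

PARAM_NAMES = ("lam", "theta", "alpha", "beta", "mu")


def _check_param(name: str) -> None:
    if name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {name!r}; expected one of {PARAM_NAMES}")


@dataclass(frozen=True)
class BifurcationDiagram:
    """Equilibrium branches along a one-parameter sweep.

    ``lower_branch`` / ``upper_branch`` hold ``n_crit`` / ``n_stable``
    per parameter value, NaN where the branch does not exist. In Case 1
    the single stable equilibrium populates the upper branch.
    """

    param_name: str
    param_values: np.ndarray
    lower_branch: np.ndarray
    upper_branch: np.ndarray
    cases: list[Case]
    base_params: SocialParams


@dataclass(frozen=True)
class FoldPoint:
    """A saddle-node point: parameter value where ``b^2 - 4ac = 0``."""

    param_name: str
    value: float
    state: float  # merged equilibrium -b/(2a)
    viable_side: str  # "below" or "above" the fold value
    discriminant_quantity: float


def sweep(p: SocialParams, param_name: str, values) -> BifurcationDiagram:
    """Solve the equilibria at each parameter value and collect branches."""
    _check_param(param_name)
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("values must be non-empty")
    if np.any(vals <= 0):
        raise ValueError("parameter values must be positive")
    if vals.size > 1 and not (np.all(np.diff(vals) > 0) or np.all(np.diff(vals) < 0)):
        raise ValueError("values must be monotone")

    lower = np.full(vals.shape, np.nan)
    upper = np.full(vals.shape, np.nan)
    cases: list[Case] = []
    for i, v in enumerate(vals):
        rep = solve_equilibria(p.replace(**{param_name: float(v)}))
        if rep.n_crit is not None:
            lower[i] = rep.n_crit
        if rep.n_stable is not None:
            upper[i] = rep.n_stable
        cases.append(rep.case)
    return BifurcationDiagram(
        param_name=param_name,
        param_values=vals,
        lower_branch=lower,
        upper_branch=upper,
        cases=cases,
        base_params=p,
    )


def _discriminant_at(p: SocialParams, param_name: str, v: float) -> float:
    return quadratic_coefficients(p.replace(**{param_name: v})).discriminant


def find_fold(
    p: SocialParams,
    param_name: str,
    bracket: tuple[float, float],
) -> FoldPoint:
    """Locate the fold by bisection of ``b^2 - 4ac`` over ``bracket``.

    The discriminant must change sign across the bracket (otherwise an
    error asks for a wider one). The root is refined to ~1e-12 relative;
    the merged state ``-b/(2a)`` and the adjacency of the Case 2 region
    are reported alongside.
    """
    _check_param(param_name)
    lo, hi = float(bracket[0]), float(bracket[1])
    if not (0 < lo < hi):
        raise ValueError("bracket must satisfy 0 < low < high")
    f_lo = _discriminant_at(p, param_name, lo)
    f_hi = _discriminant_at(p, param_name, hi)
    if f_lo == 0.0:
        fold = lo
    elif f_hi == 0.0:
        fold = hi
    elif np.sign(f_lo) == np.sign(f_hi):
        raise ValueError(
            f"discriminant does not change sign over bracket ({lo}, {hi}): "
            f"{f_lo:.4g} and {f_hi:.4g}; widen the bracket"
        )
    else:
        fold = brentq(
            lambda v: _discriminant_at(p, param_name, v),
            lo,
            hi,
            xtol=1e-13 * hi,
            rtol=8.9e-16,
        )

    at_fold = p.replace(**{param_name: fold})
    q = quadratic_coefficients(at_fold)
    state = -q.b / (2.0 * q.a)
    if state <= 0:
        raise ValueError(
            f"discriminant vanishes at {param_name}={fold:.6g} but the merged "
            f"root {state:.4g} is not positive: not a fold of the viable branch"
        )

    eps = 1e-6 * fold
    below = classify_case(p.replace(**{param_name: fold - eps}))
    above = classify_case(p.replace(**{param_name: fold + eps}))
    if (below is Case.CASE_2) == (above is Case.CASE_2):
        raise ValueError(
            f"no one-sided Case 2 region adjacent to {param_name}={fold:.6g}; "
            "bracket does not straddle the viability fold"
        )
    return FoldPoint(
        param_name=param_name,
        value=fold,
        state=state,
        viable_side="below" if below is Case.CASE_2 else "above",
        discriminant_quantity=discriminant_quantity(at_fold),
    )


def viability_region(
    p: SocialParams,
    param_x: str,
    param_y: str,
    grid_x,
    grid_y,
) -> np.ndarray:
    """Boolean matrix of the strong-Allee (Case 2) region.

    ``out[i, j]`` is True iff the model with ``param_x = grid_x[i]`` and
    ``param_y = grid_y[j]`` (all other parameters from ``p``) classifies
    as Case 2 — two positive equilibria, a viable hive with a critical
    threshold.
    """
    _check_param(param_x)
    _check_param(param_y)
    if param_x == param_y:
        raise ValueError("param_x and param_y must differ")
    gx = np.asarray(list(grid_x), dtype=float)
    gy = np.asarray(list(grid_y), dtype=float)
    if np.any(gx <= 0) or np.any(gy <= 0):
        raise ValueError("grid values must be positive")
    out = np.zeros((gx.size, gy.size), dtype=bool)
    for i, x in enumerate(gx):
        for j, y in enumerate(gy):
            q = p.replace(**{param_x: float(x), param_y: float(y)})
            out[i, j] = classify_case(q) is Case.CASE_2
    return out
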