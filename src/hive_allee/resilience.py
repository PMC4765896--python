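"""Potential function of the social hive model and basin-of-attraction
resilience metrics.

For a one-variable system ``dN/dt = m(N)`` the potential ``u`` satisfies
``u'(N) = -m(N)``: the state rolls downhill, stable equilibria sit at
local minima and the unstable critical size at the local maximum between
them ("marble in a bowl"). Integrating the social model's net rate gives

    u(N) = (alpha*beta - lam)*N + (mu/2)*N^2
           - alpha*beta^2 * ln(beta + N) + lam*theta * ln(theta + N)

(natural logarithms; the constant of integration is fixed here by the
convention ``u(0) = 0``, so values are directly comparable across
parameter sets and the barrier height from extinction is read off
directly).

Resilience of the upper stable state is quantified by the geometry of
its basin: *depth* ``u(n_crit) - u(n_stable)`` (how big a shock, in
potential units, knocks the hive over the barrier) and *width*
``n_stable - n_crit`` (how far, in bees). Both shrink as parameters
degrade — recruitment capacity down, mortality or the cooperation scales
up — and vanish at the fold. These operationalisations of the basin
language are this package's definitions; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibria import Case, EquilibriumReport, solve_equilibria
from .model_core import SocialParams

__all__ = [
    "PotentialProfile",
    "BasinSummary",
    "potential",
    "potential_profile",
    "resilience_trend",
]


def potential(n, p: SocialParams):
    """Potential ``u(N)`` of the social model, normalised so ``u(0) = 0``."""
    arr = np.asarray(n, dtype=float)
    if np.any(arr < 0):
        raise ValueError("n must be nonnegative")
    u = (
        (p.alpha * p.beta - p.lam) * arr
        + 0.5 * p.mu * arr**2
        - p.alpha * p.beta**2 * np.log(p.beta + arr)
        + p.lam * p.theta * np.log(p.theta + arr)
    )
    u0 = -p.alpha * p.beta**2 * np.log(p.beta) + p.lam * p.theta * np.log(p.theta)
    out = u - u0
    return float(out) if np.ndim(n) == 0 else out


@dataclass(frozen=True)
class PotentialProfile:
    """Gridded potential plus basin metrics for one parameter set.

    Metrics are computed from the closed-form equilibria, not from grid
    extrema; the grid exists for plotting and cross-checks. In Case 3
    (no positive equilibria) the metrics are ``None`` and ``note``
    records that the basin has disappeared.
    """

    params: SocialParams
    grid: np.ndarray
    u: np.ndarray
    report: EquilibriumReport
    barrier_height: float | None  # u(n_crit) - u(n_stable)
    barrier_from_zero: float | None  # u(n_crit) - u(0) = u(n_crit)
    basin_width: float | None  # n_stable - n_crit
    note: str = ""

    @property
    def basin_exists(self) -> bool:
        return self.barrier_height is not None


@dataclass(frozen=True)
class BasinSummary:
    """One point of a degradation sweep."""

    param_value: float
    exists: bool
    barrier_height: float | None
    basin_width: float | None


def potential_profile(
    p: SocialParams,
    n_max: float | None = None,
    n_points: int = 1000,
) -> PotentialProfile:
    """Evaluate ``u`` on a uniform grid and attach basin metrics.

    Default grid: ``[0, 1.5*n_stable]`` when an upper equilibrium exists,
    else ``[0, 3*theta]`` (wide enough to show the monotone Case 3
    profile).
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a usable profile")
    report = solve_equilibria(p)
    if n_max is None:
        n_max = 1.5 * report.n_stable if report.n_stable else 3.0 * p.theta
    if report.n_stable is not None and n_max <= report.n_stable:
        raise ValueError("n_max must exceed the upper stable equilibrium")
    grid = np.linspace(0.0, n_max, n_points)
    u = potential(grid, p)

    if report.n_crit is not None and report.n_stable is not None:
        bh = potential(report.n_crit, p) - potential(report.n_stable, p)
        bfz = potential(report.n_crit, p)
        width = report.n_stable - report.n_crit
        note = ""
    else:
        bh = bfz = width = None
        note = (
            "no basin: the upper stable equilibrium does not exist "
            f"({report.case.value}); u is monotone for N > 0"
            if report.case is Case.CASE_3
            else "single stable equilibrium; no interior barrier"
        )
    return PotentialProfile(
        params=p,
        grid=grid,
        u=u,
        report=report,
        barrier_height=bh,
        barrier_from_zero=bfz,
        basin_width=width,
        note=note,
    )


_DEGRADING_DIRECTION = {"lam": -1, "theta": +1, "alpha": +1, "beta": +1, "mu": +1}


def resilience_trend(
    p: SocialParams,
    param_name: str,
    values,
) -> list[BasinSummary]:
    """Track basin depth and width along a single-parameter sweep.

    ``values`` must be ordered in the degrading direction (``lam``
    decreasing; the others increasing). Once the fold is crossed the
    basin is gone and stays gone: every later summary has
    ``exists=False``.
    """
    if param_name not in _DEGRADING_DIRECTION:
        raise ValueError(
            f"unknown parameter {param_name!r}; expected one of "
            f"{sorted(_DEGRADING_DIRECTION)}"
        )
    vals = [float(v) for v in values]
    if len(vals) == 0:
        raise ValueError("values must be non-empty")
    direction = _DEGRADING_DIRECTION[param_name]
    diffs = np.diff(vals)
    if len(diffs) and not np.all(direction * diffs > 0):
        raise ValueError(
            f"values must be strictly {'increasing' if direction > 0 else 'decreasing'} "
            f"(the degrading direction for {param_name!r})"
        )
    out = []
    for v in vals:
        prof = potential_profile(p.replace(**{param_name: v}), n_points=100)
        out.append(
            BasinSummary(
                param_value=v,
                exists=prof.basin_exists,
                barrier_height=prof.barrier_height,
                basin_width=prof.basin_width,
            )
        )
    return out
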