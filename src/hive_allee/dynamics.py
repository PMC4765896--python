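"""Trajectories of the hive models: adaptive ODE solutions and the
daily discrete-time map, with collapse/convergence detection.

The continuous social model has no closed-form solution, so trajectories
come from an error-controlled adaptive integrator (RK45 with an LSODA
fallback; the vector field is smooth and nonstiff for sensible
parameters). The discrete recast ``N_{t+1} = N_t + m(N_t)`` with a one
day step is faithful only while daily rate increments are small; with
large rates it can propose negative hive sizes, which is surfaced
through an explicit policy rather than silently clamped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import solve_equilibria
from .model_core import (
    AsocialParams,
    SocialParams,
    asocial_rate,
    net_rate,
)

__all__ = [
    "Trajectory",
    "Attractor",
    "NegativePolicy",
    "IntegrationError",
    "integrate_ode",
    "integrate_asocial",
    "iterate_map",
    "detect_attractor",
    "COLLAPSE_THRESHOLD",
    "CONVERGENCE_RTOL",
]

#: Below one bee the continuous approximation has lost its meaning: collapsed.
COLLAPSE_THRESHOLD = 1.0
#: Relative tolerance for declaring convergence to the upper equilibrium.
CONVERGENCE_RTOL = 0.01

_RTOL = 1e-8
_ATOL = 1e-6  # bees


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the solver diagnostic message."""


class NegativePolicy(str, enum.Enum):
    ERROR = "error"
    CLAMP = "clamp"
    ALLOW = "allow"


class Attractor(str, enum.Enum):
    COLLAPSED = "collapsed"
    CONVERGED_UPPER = "converged_upper"
    UNDETERMINED = "undetermined"


@dataclass
class Trajectory:
    """A solution path: time grid (days), hive sizes, and provenance."""

    times: np.ndarray
    values: np.ndarray
    mode: str  # "ode" or "map"
    params: SocialParams | AsocialParams
    n0: float
    events: list[tuple[float, str]] = field(default_factory=list)
    solver_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")

    @property
    def final(self) -> float:
        return float(self.values[-1])


def _validate_start(n0: float, t_max: float) -> None:
    if n0 < 0:
        raise ValueError("n0 must be nonnegative")
    if t_max <= 0:
        raise ValueError("t_max must be positive")


def _solve(rhs, n0: float, t_grid: np.ndarray, rtol: float, atol: float) -> tuple[np.ndarray, dict]:
    meta: dict = {"rtol": rtol, "atol": atol}
    for method in ("RK45", "LSODA"):
        sol = solve_ivp(
            rhs,
            (t_grid[0], t_grid[-1]),
            [n0],
            t_eval=t_grid,
            method=method,
            rtol=rtol,
            atol=atol,
        )
        if sol.success:
            meta.update(method=method, nfev=int(sol.nfev))
            return sol.y[0], meta
        meta[f"{method}_failure"] = sol.message
    raise IntegrationError(f"ODE integration failed: {meta}")


def integrate_ode(
    p: SocialParams,
    n0: float,
    t_max: float,
    dt_out: float = 1.0,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> Trajectory:
    """Integrate the social model ``dN/dt = m(N)`` from ``n0``.

    Output is sampled on a uniform grid of spacing ``dt_out`` days,
    independent of the solver's internal adaptive steps. The state is
    clipped at zero only on output; ``m(0) = 0`` makes exact zero
    absorbing, so clipping only ever removes integrator roundoff.
    """
    _validate_start(n0, t_max)

    def rhs(_t, y):
        n = y[0]
        return [0.0 if n <= 0.0 else net_rate(n, p)]

    t_grid = _uniform_grid(t_max, dt_out)
    values, meta = _solve(rhs, n0, t_grid, rtol, atol)
    return Trajectory(
        times=t_grid,
        values=np.maximum(values, 0.0),
        mode="ode",
        params=p,
        n0=n0,
        solver_meta=meta,
    )


def integrate_asocial(
    p: AsocialParams,
    n0: float,
    t_max: float,
    dt_out: float = 1.0,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> Trajectory:
    """Numerically integrate the asocial baseline ``dN/dt = lam - mu*N``.

    The closed-form exponential solution serves as an external check;
    this routine goes through the same adaptive solver as the social
    model so both share one code path and one set of tolerances.
    """
    _validate_start(n0, t_max)

    def rhs(_t, y):
        return [asocial_rate(max(y[0], 0.0), p)]

    t_grid = _uniform_grid(t_max, dt_out)
    values, meta = _solve(rhs, n0, t_grid, rtol, atol)
    return Trajectory(
        times=t_grid,
        values=np.maximum(values, 0.0),
        mode="ode",
        params=p,
        n0=n0,
        solver_meta=meta,
    )


def _uniform_grid(t_max: float, dt_out: float) -> np.ndarray:
    if dt_out <= 0:
        raise ValueError("dt_out must be positive")
    n_steps = int(round(t_max / dt_out))
    if abs(n_steps * dt_out - t_max) > 1e-9 * max(t_max, 1.0):
        n_steps = int(np.ceil(t_max / dt_out))
    return np.linspace(0.0, n_steps * dt_out, n_steps + 1)


def iterate_map(
    p: SocialParams,
    n0: float,
    steps: int,
    negative_policy: NegativePolicy | str = NegativePolicy.ERROR,
) -> Trajectory:
    """Iterate the daily map ``N_{t+1} = N_t + m(N_t)`` for ``steps`` days.

    Large daily rates can overshoot below zero — dynamically absurd for
    a population count. ``negative_policy`` decides what happens then:

    * ``error`` (default): raise with a diagnostic; surfacing the regime
      beats hiding it.
    * ``clamp``: floor the state at 0 and record a ``clamped`` event.
    * ``allow``: keep the raw (negative) values, recording an event.
    """
    if n0 < 0:
        raise ValueError("n0 must be nonnegative")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    policy = NegativePolicy(negative_policy)

    values = np.empty(steps + 1)
    values[0] = n0
    events: list[tuple[float, str]] = []
    for t in range(steps):
        n = values[t]
        proposal = n + net_rate(max(n, 0.0), p) if n >= 0 else n
        if proposal < 0.0:
            if policy is NegativePolicy.ERROR:
                raise ValueError(
                    f"map proposed negative hive size {proposal:.4g} at day {t + 1} "
                    f"(from N={n:.4g}); daily rates too large for the 1-day map"
                )
            if policy is NegativePolicy.CLAMP:
                proposal = 0.0
                events.append((float(t + 1), "clamped"))
            else:
                events.append((float(t + 1), "negative"))
        values[t + 1] = proposal

    return Trajectory(
        times=np.arange(steps + 1, dtype=float),
        values=values,
        mode="map",
        params=p,
        n0=n0,
        events=events,
        solver_meta={"negative_policy": policy.value},
    )


def detect_attractor(traj: Trajectory, p: SocialParams) -> Attractor:
    """Classify where a trajectory ended up.

    ``collapsed`` if the final size is below one bee; ``converged_upper``
    if within 1% of the upper stable equilibrium (when the parameter set
    has one); otherwise ``undetermined`` — e.g. a run too short to leave
    the neighbourhood of the separatrix.
    """
    if len(traj.times) < 10:
        raise ValueError("trajectory too short to classify (need >= 10 points)")
    final = traj.final
    if final < COLLAPSE_THRESHOLD:
        return Attractor.COLLAPSED
    report = solve_equilibria(p)
    target = report.n_stable
    if target is not None and abs(final - target) <= CONVERGENCE_RTOL * target:
        return Attractor.CONVERGED_UPPER
    return Attractor.UNDETERMINED
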