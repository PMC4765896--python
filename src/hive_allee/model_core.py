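"""Rate functions for the honey-bee hive population models.

Two single-state-variable models of the number of adult bees ``N`` in a
hive, treated as a continuous nonnegative quantity with time in days:

* **Asocial baseline** — recruitment at a constant rate ``lam`` (bees/day)
  and per-individual mortality ``mu`` (1/day), so ``dN/dt = lam - mu*N``
  with closed-form solution approaching the equilibrium ``lam/mu``.

* **Social model** — both demographic rates carry a *component Allee
  effect*. Recruitment saturates, ``lam*N/(theta+N)``, because brood care
  requires adult workers (``theta`` is the hive size at half-maximal
  recruitment). Per-individual mortality declines with hive size,
  ``alpha*beta/(beta+N) + mu``, from ``mu+alpha`` in a tiny hive down to
  the asymptote ``mu`` (``beta`` is the size at which the excess mortality
  has fallen halfway).

All rate functions accept a scalar or an array of hive sizes and are the
single source of truth for every other module (equilibria, dynamics,
resilience, bifurcation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "SocialParams",
    "AsocialParams",
    "recruitment_rate",
    "mortality_rate",
    "net_rate",
    "per_capita_rate",
    "net_rate_derivative",
    "asocial_rate",
    "asocial_solution",
]


def _check_positive_finite(obj) -> None:
    bad = []
    for f in fields(obj):
        v = getattr(obj, f.name)
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            bad.append(f"{f.name}={v!r} is not a real number")
        elif not math.isfinite(v):
            bad.append(f"{f.name}={v} must be finite")
        elif v <= 0:
            bad.append(f"{f.name}={v} must be strictly positive")
    if bad:
        raise ValueError("invalid parameters: " + "; ".join(bad))


@dataclass(frozen=True)
class SocialParams:
    """Parameters of the social hive model.

    Attributes
    ----------
    lam : float
        Maximum recruitment rate (bees/day); bounded by the queen's egg
        laying capacity.
    theta : float
        Recruitment half-saturation hive size (bees); an inverse measure
        of cooperative efficiency in brood rearing.
    alpha : float
        Excess per-individual mortality at vanishing hive size (1/day).
    beta : float
        Hive size at which the excess mortality has decayed halfway
        (bees); an inverse measure of cooperative protection.
    mu : float
        Baseline per-individual mortality in a large hive (1/day).
    """

    lam: float
    theta: float
    alpha: float
    beta: float
    mu: float

    def __post_init__(self) -> None:
        _check_positive_finite(self)

    def replace(self, **kwargs: float) -> "SocialParams":
        """Return a copy with some parameters overridden (re-validated)."""
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        unknown = set(kwargs) - set(d)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        d.update(kwargs)
        return SocialParams(**d)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


@dataclass(frozen=True)
class AsocialParams:
    """Parameters of the asocial baseline: constant recruitment ``lam``
    (bees/day) and per-individual mortality ``mu`` (1/day)."""

    lam: float
    mu: float

    def __post_init__(self) -> None:
        _check_positive_finite(self)

    def as_dict(self) -> dict[str, float]:
        return {"lam": float(self.lam), "mu": float(self.mu)}

    @property
    def equilibrium(self) -> float:
        """The globally attracting hive size ``lam/mu``."""
        return self.lam / self.mu


def _asarray_nonneg(n, name: str = "n"):
    arr = np.asarray(n, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative (hive sizes are counts)")
    return arr


def _maybe_scalar(arr, like):
    return float(arr) if np.isscalar(like) or np.ndim(like) == 0 else arr


def recruitment_rate(n, p: SocialParams):
    """Recruitment rate ``lam*n/(theta+n)`` in bees/day.

    Saturating (Holling type II) in hive size: zero at ``n=0``, half of
    the maximum ``lam`` at ``n=theta``, approaching ``lam`` from below.
    """
    arr = _asarray_nonneg(n)
    out = p.lam * arr / (p.theta + arr)
    return _maybe_scalar(out, n)


def mortality_rate(n, p: SocialParams):
    """Total mortality rate ``(alpha*beta/(beta+n) + mu)*n`` in bees/day.

    The per-capita factor falls from ``mu+alpha`` at ``n=0`` to the
    asymptote ``mu`` as the hive grows.
    """
    arr = _asarray_nonneg(n)
    out = (p.alpha * p.beta / (p.beta + arr) + p.mu) * arr
    return _maybe_scalar(out, n)


def net_rate(n, p: SocialParams):
    """Net growth rate ``dN/dt`` of the social model, bees/day.

    Defined as ``recruitment_rate - mortality_rate`` exactly, so the
    algebraic identity holds to machine precision by construction.
    """
    arr = _asarray_nonneg(n)
    out = p.lam * arr / (p.theta + arr) - (p.alpha * p.beta / (p.beta + arr) + p.mu) * arr
    return _maybe_scalar(out, n)


def per_capita_rate(n, p: SocialParams):
    """Per-individual net rate ``lam/(theta+n) - alpha*beta/(beta+n) - mu``.

    At ``n=0`` this is the continuous extension ``lam/theta - alpha - mu``,
    the quantity whose sign relative to zero separates the dynamical
    cases. The curve rises at low ``n`` (the Allee signature) before
    falling toward the asymptote ``-mu``.
    """
    arr = _asarray_nonneg(n)
    out = p.lam / (p.theta + arr) - p.alpha * p.beta / (p.beta + arr) - p.mu
    return _maybe_scalar(out, n)


def net_rate_derivative(n, p: SocialParams):
    """Closed-form slope ``d(net_rate)/dN``.

    ``m'(N) = lam*theta/(theta+N)^2 - alpha*beta^2/(beta+N)^2 - mu``;
    its sign at an equilibrium decides stability.
    """
    arr = _asarray_nonneg(n)
    out = (
        p.lam * p.theta / (p.theta + arr) ** 2
        - p.alpha * p.beta**2 / (p.beta + arr) ** 2
        - p.mu
    )
    return _maybe_scalar(out, n)


def asocial_rate(n, p: AsocialParams):
    """Net growth rate ``lam - mu*n`` of the asocial baseline, bees/day."""
    arr = _asarray_nonneg(n)
    out = p.lam - p.mu * arr
    return _maybe_scalar(out, n)


def asocial_solution(t, n0: float, p: AsocialParams):
    """Closed-form hive size of the asocial model at time(s) ``t`` days.

    ``N(t) = lam/mu + (n0 - lam/mu) * exp(-mu*t)`` — monotone relaxation
    toward the equilibrium ``lam/mu`` with time constant ``1/mu``.
    """
    t_arr = _asarray_nonneg(t, "t")
    if n0 < 0:
        raise ValueError("n0 must be nonnegative")
    eq = p.lam / p.mu
    out = eq + (n0 - eq) * np.exp(-p.mu * t_arr)
    return _maybe_scalar(out, t)
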