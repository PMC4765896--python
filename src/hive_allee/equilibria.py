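"""Closed-form equilibria, case classification, and stability.

Setting the social model's net rate to zero gives ``N=0`` plus the roots
of a quadratic ``a*N^2 + b*N + c = 0`` with

    a = -mu
    b = lam - alpha*beta - mu*theta - mu*beta
    c = beta * (lam - alpha*theta - mu*theta)

Three dynamical cases arise from the per-capita rate geometry:

* **Case 1** (``lam/theta > alpha+mu``): recruitment exceeds mortality at
  vanishing size; a single positive, globally stable equilibrium (weak
  Allee effect).
* **Case 2** (``lam/theta < alpha+mu`` but above ``mu``, with the
  quadratic discriminant positive and ``b > 0``): two positive equilibria
  — a lower unstable critical size below which the hive collapses, and an
  upper stable size (strong Allee effect). Zero is also stable.
* **Case 3**: mortality dominates everywhere; every trajectory collapses.

The dimensionless *discriminant quantity*

    b^2 / (4*mu*beta*(mu*theta + alpha*theta - lam))

exceeds 1 exactly when the discriminant ``b^2 - 4ac`` is positive
(provided its denominator is positive, i.e. ``c < 0``); it is increasing
in ``lam`` and decreasing in ``theta``, ``beta``, ``alpha`` and ``mu``,
so any degradation of hive function pushes it toward the fold at 1.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .model_core import SocialParams, net_rate, net_rate_derivative

__all__ = [
    "Case",
    "Stability",
    "QuadraticCoefficients",
    "Equilibrium",
    "EquilibriumReport",
    "quadratic_coefficients",
    "discriminant_quantity",
    "classify_case",
    "solve_equilibria",
    "stability",
]

#: A root is accepted as an equilibrium if |net_rate(root)| <= EQ_TOL * lam.
#: Scaling by lam (the largest rate in the model) makes the test unit-free.
EQ_TOL = 1e-8

#: |m'(N)| below this (relative to mu) is reported as degenerate.
DEGENERATE_TOL = 1e-10


class Case(str, enum.Enum):
    CASE_1 = "CASE_1"
    CASE_2 = "CASE_2"
    CASE_3 = "CASE_3"


class Stability(str, enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    DEGENERATE = "degenerate"


@dataclass(frozen=True)
class QuadraticCoefficients:
    """Coefficients of the equilibrium quadratic ``a*N^2 + b*N + c``."""

    a: float  # = -mu, always negative
    b: float
    c: float

    @property
    def discriminant(self) -> float:
        return self.b * self.b - 4.0 * self.a * self.c


@dataclass(frozen=True)
class Equilibrium:
    value: float
    stability: Stability


@dataclass(frozen=True)
class EquilibriumReport:
    """Full account of the social model's equilibrium structure."""

    params: SocialParams
    coefficients: QuadraticCoefficients
    discriminant: float
    discriminant_quantity: float  # NaN on the c=0 boundary
    boundary_c_zero: bool
    case: Case
    equilibria: list[Equilibrium] = field(default_factory=list)
    n_crit: float | None = None
    n_stable: float | None = None

    @property
    def zero_equilibrium(self) -> Equilibrium:
        return next(e for e in self.equilibria if e.value == 0.0)

    @property
    def positive_roots(self) -> list[float]:
        return [e.value for e in self.equilibria if e.value > 0.0]

    def to_dict(self) -> dict:
        return {
            "a": self.coefficients.a,
            "b": self.coefficients.b,
            "c": self.coefficients.c,
            "discriminant": self.discriminant,
            "discriminant_quantity": self.discriminant_quantity,
            "case": self.case.value,
            "equilibria": [
                {"value": e.value, "stability": e.stability.value}
                for e in self.equilibria
            ],
        }


def quadratic_coefficients(p: SocialParams) -> QuadraticCoefficients:
    """Evaluate the equilibrium quadratic's coefficients in closed form."""
    a = -p.mu
    b = p.lam - p.alpha * p.beta - p.mu * p.theta - p.mu * p.beta
    c = p.beta * (p.lam - p.alpha * p.theta - p.mu * p.theta)
    return QuadraticCoefficients(a=a, b=b, c=c)


def discriminant_quantity(p: SocialParams) -> float:
    """Dimensionless collapse-proximity index.

    ``b^2 / (4*mu*beta*(mu*theta + alpha*theta - lam))``; values above 1
    mean the two positive equilibria exist (when the denominator is
    positive), and the fold — where they merge and vanish — sits exactly
    at 1. Returns NaN on the measure-zero boundary where the denominator
    vanishes (equivalently ``c = 0``), which callers should treat as a
    flagged boundary case rather than a failure.
    """
    q = quadratic_coefficients(p)
    denom = 4.0 * p.mu * p.beta * (p.mu * p.theta + p.alpha * p.theta - p.lam)
    if denom == 0.0:
        return math.nan
    return q.b * q.b / denom


def classify_case(p: SocialParams) -> Case:
    """Classify the parameter set into one of the three dynamical cases.

    Boundary equalities (``lam/theta == alpha+mu``, zero discriminant
    with a nonpositive repeated root, ``b == 0``) fall to CASE_3 — they
    are measure-zero — except the repeated-positive-root fold, which is
    classified CASE_2 (its degenerate equilibrium is dynamically
    meaningful and is labelled as such by :func:`solve_equilibria`).
    """
    intercept = p.lam / p.theta
    if intercept > p.alpha + p.mu:
        return Case.CASE_1
    q = quadratic_coefficients(p)
    disc = q.discriminant
    if (
        intercept < p.alpha + p.mu
        and intercept > p.mu
        and q.b > 0.0
        and disc >= 0.0
    ):
        # disc == 0 is the fold: a repeated positive root -b/(2a).
        return Case.CASE_2
    return Case.CASE_3


def stability(n_eq: float, p: SocialParams, tol: float = EQ_TOL) -> Stability:
    """Stability of an equilibrium from the sign of ``m'(N)``.

    Raises if ``n_eq`` is not an equilibrium (``|m(n_eq)| > tol*lam``).
    """
    if abs(net_rate(n_eq, p)) > tol * p.lam:
        raise ValueError(
            f"n={n_eq} is not an equilibrium: |net_rate|={abs(net_rate(n_eq, p)):.3g} "
            f"exceeds {tol * p.lam:.3g}"
        )
    slope = net_rate_derivative(n_eq, p)
    if abs(slope) <= DEGENERATE_TOL * p.mu:
        return Stability.DEGENERATE
    return Stability.STABLE if slope < 0 else Stability.UNSTABLE


def solve_equilibria(p: SocialParams) -> EquilibriumReport:
    """All nonnegative equilibria of the social model, with stability.

    ``N=0`` is always an equilibrium. Positive roots come from the
    quadratic formula; with ``a < 0`` the printed root expressions order
    inversely, so the critical size ``n_crit`` is defined as the
    *smaller* positive root and ``n_stable`` as the larger, matching the
    dynamics (lower unstable, upper stable). A repeated positive root at
    the fold is reported once, labelled degenerate.
    """
    q = quadratic_coefficients(p)
    disc = q.discriminant
    roots: list[float] = []
    if disc > 0.0:
        # Citardauq-style pairing avoids cancellation when |b| >> sqrt(|4ac|).
        sq = math.sqrt(disc)
        qq = -0.5 * (q.b + math.copysign(sq, q.b)) if q.b != 0.0 else -0.5 * sq
        r1 = qq / q.a
        r2 = q.c / qq if qq != 0.0 else 0.0
        roots = sorted(r for r in (r1, r2) if r > 0.0)
    elif disc == 0.0:
        r = -q.b / (2.0 * q.a)
        if r > 0.0:
            roots = [r]

    equilibria = [Equilibrium(0.0, stability(0.0, p))]
    n_crit = n_stable = None
    if disc == 0.0 and roots:
        equilibria.append(Equilibrium(roots[0], Stability.DEGENERATE))
    elif len(roots) == 1:
        # Case 1: single positive root (c > 0 makes the roots straddle 0).
        equilibria.append(Equilibrium(roots[0], stability(roots[0], p)))
        n_stable = roots[0]
    elif len(roots) == 2:
        n_crit, n_stable = roots
        equilibria.append(Equilibrium(n_crit, stability(n_crit, p)))
        equilibria.append(Equilibrium(n_stable, stability(n_stable, p)))

    return EquilibriumReport(
        params=p,
        coefficients=q,
        discriminant=disc,
        discriminant_quantity=discriminant_quantity(p),
        boundary_c_zero=(q.c == 0.0),
        case=classify_case(p),
        equilibria=equilibria,
        n_crit=n_crit,
        n_stable=n_stable,
    )
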