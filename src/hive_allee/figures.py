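"""Qualitative reproduction of the model's standard figure set.

Seven figures built from the bundled fixtures: asocial relaxation,
the four rate functions, the three dynamical cases with Case 2
trajectories, the per-capita Allee curves, the equilibrium quadratics
under parameter change, the double-well potential, and the degrading
potential sequence. Parameter values are the package fixtures, so the
figures are structurally faithful (curve counts, crossings, monotone
trends) rather than numeric reproductions of any published plot.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .config import fixtures
from .dynamics import integrate_asocial, integrate_ode
from .equilibria import quadratic_coefficients, solve_equilibria
from .model_core import (
    AsocialParams,
    mortality_rate,
    per_capita_rate,
    recruitment_rate,
)
from .resilience import potential, potential_profile

__all__ = ["render_figures"]

_FILES = (
    "fig1_asocial_trajectories.png",
    "fig2_rate_functions.png",
    "fig3_cases_and_trajectories.png",
    "fig4_per_capita_allee.png",
    "fig5_quadratic_roots.png",
    "fig6_potential.png",
    "fig7_degrading_potentials.png",
)


def render_figures(out_dir: str | Path) -> list[Path]:
    """Render all seven figures into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = fixtures()
    p2 = fx["case2_default"]
    paths = [out / name for name in _FILES]

    _fig1_asocial(paths[0])
    _fig2_rates(paths[1], p2)
    _fig3_cases(paths[2], fx)
    _fig4_per_capita(paths[3], fx)
    _fig5_quadratics(paths[4], p2)
    _fig6_potential(paths[5], p2)
    _fig7_degrading(paths[6], p2)
    return paths


def _fig1_asocial(path: Path) -> None:
    p = AsocialParams(lam=500.0, mu=0.04)
    fig, ax = plt.subplots(figsize=(6, 4))
    for n0 in (1000.0, 5000.0, 12500.0, 20000.0):
        traj = integrate_asocial(p, n0, t_max=150.0)
        ax.plot(traj.times, traj.values, "k-", lw=1)
    ax.axhline(p.equilibrium, ls="--", color="grey")
    ax.set(xlabel="time (days)", ylabel="adult bees",
           title="Asocial model: relaxation to lam/mu")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig2_rates(path: Path, p) -> None:
    n = np.linspace(0.0, 60000.0, 400)
    npos = n[1:]
    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    axes[0, 0].plot(n, recruitment_rate(n, p))
    axes[0, 0].axhline(p.lam, ls="--", color="grey", label=f"asymptote lam={p.lam:g}")
    axes[0, 0].legend(fontsize=8)
    axes[0, 0].set_title("recruitment rate")
    axes[0, 1].plot(npos, p.lam / (p.theta + npos))
    axes[0, 1].set_title("per-individual recruitment")
    axes[1, 0].plot(n, mortality_rate(n, p))
    axes[1, 0].set_title("mortality rate")
    axes[1, 1].plot(n, p.alpha * p.beta / (p.beta + n) + p.mu)
    axes[1, 1].axhline(p.mu, ls="--", color="grey", label=f"asymptote mu={p.mu:g}")
    axes[1, 1].legend(fontsize=8)
    axes[1, 1].set_title("per-individual mortality")
    for ax in axes.flat:
        ax.set_xlabel("adult bees")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig3_cases(path: Path, fx) -> None:
    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    for ax, key in zip(axes.flat[:3], ("case1", "case2_default", "case3")):
        p = fx[key]
        n = np.linspace(0.0, 60000.0, 400)
        ax.plot(n, p.lam / (p.theta + n), "-", label="recruitment")
        ax.plot(n, p.alpha * p.beta / (p.beta + n) + p.mu, "--", label="mortality")
        ax.set_title(key)
        ax.legend(fontsize=8)
        ax.set_xlabel("adult bees")
        ax.set_ylabel("per-individual rate (1/day)")
    p2 = fx["case2_default"]
    rep = solve_equilibria(p2)
    ax = axes.flat[3]
    for frac in (0.4, 0.9, 1.1, 2.0, 8.0, 30.0):
        traj = integrate_ode(p2, frac * rep.n_crit, t_max=600.0)
        ax.plot(traj.times, traj.values, "k-", lw=1)
    ax.axhline(rep.n_crit, ls=":", color="red")
    ax.axhline(rep.n_stable, ls="--", color="grey")
    ax.set_title("Case 2 trajectories")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("adult bees")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig4_per_capita(path: Path, fx) -> None:
    n = np.linspace(0.0, 60000.0, 600)
    fig, ax = plt.subplots(figsize=(6, 4))
    styles = {"case1": (0, (6, 2)), "case2_default": "solid", "case3": (0, (2, 2))}
    for key, ls in styles.items():
        ax.plot(n, per_capita_rate(n, fx[key]), ls=ls, label=key, color="k")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set(xlabel="adult bees", ylabel="per-individual net rate (1/day)",
           title="Allee effect: rising per-capita growth at low size")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig5_quadratics(path: Path, p) -> None:
    panels = [("lam", (2000.0, 1500.0, 1100.0)),
              ("mu", (0.02, 0.03, 0.04)),
              ("theta", (16000.0, 24000.0, 34000.0)),
              ("beta", (5000.0, 12000.0, 25000.0))]
    n = np.linspace(0.0, 60000.0, 400)
    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    for ax, (name, vals) in zip(axes.flat, panels):
        for v in vals:
            q = quadratic_coefficients(p.replace(**{name: v}))
            ax.plot(n, q.a * n**2 + q.b * n + q.c, label=f"{name}={v:g}")
        ax.axhline(0.0, ls="--", color="grey")
        ax.set_title(f"varying {name}")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig6_potential(path: Path, p) -> None:
    prof = potential_profile(p)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(prof.grid, prof.u, "k-")
    rep = prof.report
    ax.axvline(rep.n_crit, ls=":", color="red", label="critical size")
    ax.axvline(rep.n_stable, ls="--", color="grey", label="stable size")
    ax.set(xlabel="adult bees", ylabel="potential u(N)",
           title="Double-well potential (strong Allee effect)")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig7_degrading(path: Path, p) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    n = np.linspace(0.0, 60000.0, 500)
    for mu in (0.02, 0.027, 0.034, 0.0372, 0.042):
        ax.plot(n, potential(n, p.replace(mu=mu)), label=f"mu={mu:g}")
    ax.set(xlabel="adult bees", ylabel="potential u(N)",
           title="Degrading mortality: the upper basin fills in and vanishes")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)
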