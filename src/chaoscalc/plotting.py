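"""Matplotlib views of stretch curves, CHAOS profiles and GA histories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt

from .evolve import EvolutionHistory
from .mechanics import StretchCurve

__all__ = ["plot_stretch_curves", "plot_chaos_profile", "plot_evolution_history"]


def plot_stretch_curves(reference: StretchCurve, peptide: StretchCurve, ax=None):
    """Tension versus relative strain for the paired systems; the enclosed
    area between the curves is the sensing free energy."""
    if ax is None:
        _, ax = plt.subplots()
    for curve, style in ((reference, "ko-"), (peptide, "o-")):
        ax.errorbar(
            curve.strains * 100,
            curve.sigmas,
            yerr=curve.sems,
            fmt=style,
            label=curve.label or None,
            capsize=2,
        )
    ax.set_xlabel("relative strain (%)")
    ax.set_ylabel("surface tension (mN/m)")
    ax.legend()
    return ax


def plot_chaos_profile(profile, ax=None):
    """CHAOS against the reference tension difference for each end-state
    choice; flat profiles demonstrate end-state invariance."""
    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(
        [p.delta_sigma for p in profile],
        [p.chaos for p in profile],
        yerr=[p.chaos_err for p in profile],
        fmt="s-",
        capsize=2,
    )
    ax.set_xlabel(r"$\Delta\sigma$ (mN/m)")
    ax.set_ylabel(r"CHAOS (nm$^2$)")
    return ax


def plot_evolution_history(history: EvolutionHistory, ax=None):
    """Best and mean fitness per generation of a GA run."""
    if ax is None:
        _, ax = plt.subplots()
    gens = [g.generation for g in history.generations]
    ax.plot(gens, [g.best_fitness for g in history.generations], label="best")
    ax.plot(gens, [g.mean_fitness for g in history.generations], "--", label="mean")
    ax.set_xlabel("generation")
    ax.set_ylabel("fitness")
    ax.legend()
    return ax
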