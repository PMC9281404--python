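"""Thermodynamic integration and the mechanical/alchemical cycle check.

Alchemical decoupling transitions a membrane-bound peptide (lambda = 0,
fully coupled) to the peptide in vacuo (lambda = 1) separately for the van
der Waals and Coulomb interactions; the free energy of each leg is the
integral of <dV/dlambda> over the coupling parameter.  The difference of
the two tension states' totals is the alchemical sensing free energy, which
closes a thermodynamic cycle with the mechanical end-state estimate.  The
closure test follows common practice: a two-tailed Welch's (unequal
variance) t test between the two estimates, "closed" when p > 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.integrate import simpson

from .mechanics import SensingResult, ValueWithError

__all__ = [
    "LambdaLeg",
    "TIResult",
    "CycleClosureReport",
    "ti_integrate",
    "binding_free_energy",
    "alchemical_sensing",
    "cycle_closure",
    "welch_t",
    "simulation_count",
]

TENSION_STATES = ("A0", "A")


@dataclass
class LambdaLeg:
    """One decoupling leg: a lambda grid with <dV/dlambda> means and SEMs."""

    leg: str  # {"vdw", "coulomb"}
    lambdas: np.ndarray
    dvdl_mean: np.ndarray
    dvdl_sem: np.ndarray
    tension_state: str  # {"A0", "A"}

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.dvdl_mean = np.asarray(self.dvdl_mean, dtype=float)
        self.dvdl_sem = np.asarray(self.dvdl_sem, dtype=float)
        if self.leg not in ("vdw", "coulomb"):
            raise ValueError(f"unknown leg {self.leg!r}")
        if self.tension_state not in TENSION_STATES:
            raise ValueError(f"tension_state must be one of {TENSION_STATES}")
        n = self.lambdas.size
        if n < 2:
            raise ValueError("need at least two lambda points")
        if self.dvdl_mean.size != n or self.dvdl_sem.size != n:
            raise ValueError("lambda grid and dV/dlambda arrays differ in length")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("lambda grid must be strictly increasing")
        if self.lambdas[0] < 0 or self.lambdas[-1] > 1:
            raise ValueError("lambdas must lie in [0, 1]")
        if abs(self.lambdas[0]) > 1e-12 or abs(self.lambdas[-1] - 1) > 1e-12:
            raise ValueError("lambda grid must span [0, 1] (endpoints included)")
        if np.any(self.dvdl_sem < 0):
            raise ValueError("SEMs must be non-negative")

    @property
    def n_lambdas(self) -> int:
        return self.lambdas.size


@dataclass
class TIResult:
    """Integrated free energy of one state: per-leg values and their sum."""

    dF_per_leg: dict[str, float]
    dF_total: float
    dF_err: float
    n_lambdas: int
    tension_state: str
    smoothness: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.dF_per_leg.values()) - self.dF_total) > 1e-9 * max(
            1.0, abs(self.dF_total)
        ):
            raise ValueError("dF_total must equal the sum over legs")

    def to_dict(self) -> dict:
        return {
            "dF_per_leg_kJ_per_mol": dict(self.dF_per_leg),
            "dF_total_kJ_per_mol": self.dF_total,
            "dF_err_kJ_per_mol": self.dF_err,
            "n_lambdas": self.n_lambdas,
            "tension_state": self.tension_state,
            "smoothness_kJ_per_mol": self.smoothness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TIResult":
        return cls(
            dF_per_leg=dict(d["dF_per_leg_kJ_per_mol"]),
            dF_total=d["dF_total_kJ_per_mol"],
            dF_err=d["dF_err_kJ_per_mol"],
            n_lambdas=d["n_lambdas"],
            tension_state=d["tension_state"],
            smoothness=d.get("smoothness_kJ_per_mol", 0.0),
        )


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.zeros_like(x)
    w[0] = 0.5 * (x[1] - x[0])
    w[-1] = 0.5 * (x[-1] - x[-2])
    if x.size > 2:
        w[1:-1] = 0.5 * (x[2:] - x[:-2])
    return w


def ti_integrate(leg: LambdaLeg, method: str = "trapezoid") -> ValueWithError:
    """Integrate <dV/dlambda> over [0, 1] for one leg.

    ``trapezoid`` (default) is exact for affine profiles; ``simpson``
    (odd point counts) for quadratics.  The error is the quadrature of the
    per-lambda SEMs with trapezoid weights; the smoothness diagnostic (max
    absolute second difference, a proxy for grid adequacy) is available via
    :func:`smoothness_diagnostic`.
    """
    lam, y = leg.lambdas, leg.dvdl_mean
    if method == "trapezoid":
        value = float(np.trapezoid(y, lam))
    elif method == "simpson":
        if lam.size % 2 == 0:
            raise ValueError("simpson integration needs an odd number of lambda points")
        value = float(simpson(y, x=lam))
    else:
        raise ValueError(f"unknown integration method {method!r}")
    w = _trapezoid_weights(lam)
    err = float(np.sqrt(np.sum((w * leg.dvdl_sem) ** 2)))
    return ValueWithError(value, err)


def smoothness_diagnostic(leg: LambdaLeg) -> float:
    """Max absolute second difference of the dV/dlambda profile (kJ/mol).

    Large values flag a profile too rough for reliable numerical
    integration on the given lambda grid.
    """
    if leg.n_lambdas < 3:
        return 0.0
    return float(np.max(np.abs(np.diff(leg.dvdl_mean, n=2))))


def binding_free_energy(
    vdw: LambdaLeg, coulomb: LambdaLeg, method: str = "trapezoid"
) -> TIResult:
    """Sum the van der Waals and Coulomb leg integrals for one tension state."""
    if vdw.tension_state != coulomb.tension_state:
        raise ValueError(
            f"legs come from different tension states "
            f"({vdw.tension_state!r} vs {coulomb.tension_state!r})"
        )
    per_leg, errs = {}, []
    for leg in (vdw, coulomb):
        val, err = ti_integrate(leg, method=method)
        per_leg[leg.leg] = val
        errs.append(err)
    total = float(sum(per_leg.values()))
    return TIResult(
        dF_per_leg=per_leg,
        dF_total=total,
        dF_err=float(np.hypot(*errs)),
        n_lambdas=vdw.n_lambdas,
        tension_state=vdw.tension_state,
        smoothness=max(smoothness_diagnostic(vdw), smoothness_diagnostic(coulomb)),
    )


def alchemical_sensing(dFb_prime: TIResult, dFb: TIResult) -> ValueWithError:
    """Alchemical sensing free energy ddF = dF'_b(stretched) - dF_b(tensionless)."""
    if dFb_prime.tension_state != "A":
        raise ValueError("dFb_prime must come from the stretched state 'A'")
    if dFb.tension_state != "A0":
        raise ValueError("dFb must come from the tensionless state 'A0'")
    return ValueWithError(
        dFb_prime.dF_total - dFb.dF_total,
        float(np.hypot(dFb_prime.dF_err, dFb.dF_err)),
    )


def welch_t(
    mean1: float, sem1: float, n1: int, mean2: float, sem2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic, Welch-Satterthwaite df, and
    two-tailed p, from means, standard errors and replicate counts."""
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("Welch's t needs positive standard errors")
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch's t needs at least two replicates per group")
    se2 = sem1**2 + sem2**2
    t = (mean1 - mean2) / np.sqrt(se2)
    df = se2**2 / (sem1**4 / (n1 - 1) + sem2**4 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


@dataclass
class CycleClosureReport:
    """Comparison of mechanical and alchemical sensing free energies."""

    mech: float
    alch: float
    difference: float
    combined_err: float
    t: float | None
    df: float | None
    p: float | None
    closed: bool
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "mechanical_kJ_per_mol": self.mech,
            "alchemical_kJ_per_mol": self.alch,
            "difference_kJ_per_mol": self.difference,
            "combined_err_kJ_per_mol": self.combined_err,
            "welch_t": self.t,
            "welch_df": self.df,
            "p_two_tailed": self.p,
            "closed": self.closed,
            "note": self.note,
        }


def cycle_closure(
    mech: SensingResult | tuple[float, float],
    alch: tuple[float, float],
    n_mech: int,
    n_alch: int,
    alpha: float = 0.05,
) -> CycleClosureReport:
    """Welch's-t consistency test between the two pathways.

    The cycle is "closed" when the two-tailed p exceeds ``alpha`` (0.05 by
    convention).  Zero-variance inputs with a nonzero difference are
    reported as non-closed with an undefined p.
    """
    if isinstance(mech, SensingResult):
        m_val, m_err = mech.ddF, mech.ddF_err
    else:
        m_val, m_err = mech
    a_val, a_err = alch
    diff = m_val - a_val
    combined = float(np.hypot(m_err, a_err))
    if m_err <= 0 or a_err <= 0:
        if diff == 0:
            return CycleClosureReport(
                m_val, a_val, diff, combined, None, None, None,
                closed=True, note="exact agreement with zero variance",
            )
        return CycleClosureReport(
            m_val, a_val, diff, combined, None, None, None,
            closed=False, note="zero variance with nonzero difference; p undefined",
        )
    t, df, p = welch_t(m_val, m_err, n_mech, a_val, a_err, n_alch)
    return CycleClosureReport(m_val, a_val, diff, combined, t, df, p, closed=p > alpha)


def simulation_count(
    n_lambdas: int = 37, n_legs: int = 2, n_tension_states: int = 2
) -> int:
    """Number of decoupling simulations a full TI campaign needs.

    Separate van der Waals/Coulomb decoupling at every lambda state,
    repeated for the tensionless and stretched membranes: with the default
    37-state grid this is 37 x 2 x 2 = 148 runs — the cost the mechanical
    end-state route avoids.
    """
    if min(n_lambdas, n_legs, n_tension_states) < 1:
        raise ValueError("counts must be positive")
    return n_lambdas * n_legs * n_tension_states
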