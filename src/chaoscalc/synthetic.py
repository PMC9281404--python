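"""Cycle-consistent synthetic data with closed-form ground truth.

The generator emulates the reduced observables of constant-area membrane
simulations with a Hookean membrane + peptide model:

    sigma(A) = s * K_A * (A - A0 - dA_p) / A0,

where ``dA_p`` is the excess leaflet area a bound peptide injects and
``s`` in (0, 1] softens the modulus (K_A' = s * K_A; the peptide-free
reference has s = 1, dA_p = 0).  From this law the sensing free energy and
CHAOS parameter have closed forms (see :func:`closed_form_sensing`), so
every downstream estimator can be checked against exact ground truth.

Pressure traces are built by inverting the tension relation: the model
tension plus AR(1) noise (amplitude = stationary standard deviation,
correlation time tau_corr) is decomposed into diagonal pressures with
P_zz pinned at 1 bar, mimicking z-only pressure coupling.  Matching TI
lambda-legs are scaled smooth profiles whose integrals close the
mechanical/alchemical thermodynamic cycle by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from . import units
from .alchemy import LambdaLeg
from .mechanics import StretchCurve, relative_strain
from .tension import PressureTrace, TensionEstimate, estimate_tension

__all__ = [
    "HookeanMembraneModel",
    "CycleSpec",
    "model_tension",
    "closed_form_sensing",
    "simulate_pressure_trace",
    "generate_stretch_curves",
    "simulate_dhdl",
    "DEFAULT_AREAS",
]

#: The six production areas (nm^2): 42.4 to 49.4 in steps of 1.4.
DEFAULT_AREAS = tuple(42.4 + 1.4 * i for i in range(6))

#: Reference normal pressure (bar), the barostat set point.
P_REF = 1.0


@dataclass(frozen=True)
class HookeanMembraneModel:
    """Hookean membrane (+ optional bound peptide) generating model.

    Defaults describe a small coarse-grained POPC patch: tensionless area
    42.4 nm^2, modulus 240 mN/m, box height 10 nm, frames every 10 ps with
    tension fluctuations of 50 mN/m standard deviation decorrelating over
    100 ps.  ``dA_p`` = 0 and ``softening`` = 1 give the peptide-free
    reference.
    """

    A0: float = 42.4          # nm^2, tensionless reference area
    K_A: float = 240.0        # mN/m, area compressibility modulus
    dA_p: float = 0.0         # nm^2, peptide excess area
    softening: float = 1.0    # dimensionless, K_A' = softening * K_A
    noise_amp: float = 50.0   # mN/m, stationary sd of tension fluctuations
    tau_corr: float = 100.0   # ps, AR(1) correlation time
    Lz: float = 10.0          # nm, box height
    dt: float = 10.0          # ps, output interval

    def __post_init__(self) -> None:
        if min(self.A0, self.K_A, self.Lz, self.dt) <= 0:
            raise ValueError("A0, K_A, Lz and dt must be positive")
        if not 0 < self.softening <= 1:
            raise ValueError("softening must lie in (0, 1]")
        if self.dA_p < 0:
            raise ValueError("peptide excess area must be non-negative")
        if self.noise_amp < 0 or self.tau_corr <= 0:
            raise ValueError("noise_amp must be >= 0 and tau_corr > 0")

    @property
    def is_reference(self) -> bool:
        return self.dA_p == 0 and self.softening == 1.0

    def reference(self) -> "HookeanMembraneModel":
        """The matching peptide-free membrane (same elasticity and noise)."""
        return replace(self, dA_p=0.0, softening=1.0)


def model_tension(model: HookeanMembraneModel, area: float) -> float:
    """Mean tension (mN/m) of the model membrane held at ``area``."""
    if area <= 0:
        raise ValueError("area must be positive")
    return model.softening * model.K_A * (area - model.A0 - model.dA_p) / model.A0


def closed_form_sensing(
    model_pep: HookeanMembraneModel, area_end: float
) -> tuple[float, float, float]:
    """Exact (ddF kJ/mol, dsigma mN/m, CHAOS nm^2) for end states (A0, A).

    With dA = A - A0, s the softening and the peptide-free reference
    sharing K_A and A0:

        ddF    = (K_A/A0) * [ (s-1) dA^2 / 2 - s dA_p dA ]   (mN/m nm^2)
        dsigma = -K_A dA / A0
        CHAOS  = (1-s) dA / 2 + s dA_p

    CHAOS reduces to the injected excess area dA_p for a pure area shift
    (s = 1) and is then end-state invariant.
    """
    da = area_end - model_pep.A0
    s, dap = model_pep.softening, model_pep.dA_p
    ddf_mn = (model_pep.K_A / model_pep.A0) * ((s - 1.0) * da**2 / 2.0 - s * dap * da)
    dsigma = -model_pep.K_A * da / model_pep.A0
    chaos = (1.0 - s) * da / 2.0 + s * dap
    return units.mech_work_to_kj_per_mol(ddf_mn), dsigma, chaos


def _ar1(n: int, amp: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with sd ``amp`` and lag-1 coefficient ``phi``."""
    if amp == 0:
        return np.zeros(n)
    innov_sd = amp * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    x0 = rng.normal(0.0, amp)  # stationary start
    out, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    return out


def simulate_pressure_trace(
    model: HookeanMembraneModel,
    area: float,
    n_frames: int,
    seed: int | np.random.SeedSequence,
    label: str = "",
) -> PressureTrace:
    """Emit a pressure-tensor trace whose per-frame tension is the model's.

    The per-frame tension sigma(t) = model mean + AR(1) noise is decomposed
    into diagonal pressures with P_zz fixed at 1 bar and P_xx = P_yy =
    P_zz - sigma(t)/L_z (in bar, sigma in bar*nm), so recomputing the
    tension from the emitted pressures recovers sigma(t) exactly.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    phi = float(np.exp(-model.dt / model.tau_corr))
    sigma_mn = model_tension(model, area) + _ar1(n_frames, model.noise_amp, phi, rng)
    sigma_bar_nm = units.mn_per_m_to_bar_nm(sigma_mn)
    pzz = np.full(n_frames, P_REF)
    pxx = pzz - sigma_bar_nm / model.Lz
    time = model.dt * np.arange(n_frames)
    return PressureTrace(
        time=time,
        pxx=pxx,
        pyy=pxx.copy(),
        pzz=pzz,
        lz=model.Lz,
        area=area,
        label=label,
        surften=sigma_bar_nm.copy(),
    )


def generate_stretch_curves(
    model_ref: HookeanMembraneModel,
    model_pep: HookeanMembraneModel,
    areas: Sequence[float] = DEFAULT_AREAS,
    n_frames: int = 20_000,
    seed: int | np.random.SeedSequence = 0,
    t_discard: float = 0.0,
    n_blocks: int = 5,
) -> tuple[StretchCurve, StretchCurve]:
    """Paired (reference, peptide) stretch curves over one area grid.

    Each point is an independent simulated run analyzed with the standard
    trim/block-average pipeline; sub-seeds are spawned deterministically
    from ``seed``.  ``areas`` must include the models' shared A0.
    """
    if model_ref.A0 != model_pep.A0:
        raise ValueError("reference and peptide models must share A0")
    areas = sorted(float(a) for a in areas)
    if abs(areas[0] - model_ref.A0) > 1e-9:
        raise ValueError("the area grid must start at the tensionless area A0")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    children = ss.spawn(2 * len(areas))
    curves = []
    for offset, (model, label) in enumerate([(model_ref, "reference"), (model_pep, "peptide")]):
        ests = []
        for i, a in enumerate(areas):
            trace = simulate_pressure_trace(
                model, a, n_frames, children[2 * i + offset], label=label
            )
            ests.append(estimate_tension(trace, t_discard=t_discard, n_blocks=n_blocks))
        curves.append(StretchCurve.from_tensions(ests, area0=model.A0, label=label))
    return curves[0], curves[1]


@dataclass(frozen=True)
class CycleSpec:
    """Specification of a closed mechanical/alchemical thermodynamic cycle.

    ``dF_solvation`` is the peptide-state-independent baseline (solvation
    terms cancel between the two tension states); the stretched-state TI
    total then differs from the tensionless one by exactly the model's
    closed-form mechanical sensing free energy.
    """

    model: HookeanMembraneModel
    A_end: float = DEFAULT_AREAS[-1]
    dF_solvation: float = -300.0  # kJ/mol
    lambda_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.linspace(0.0, 1.0, 37))
    )

    def __post_init__(self) -> None:
        if self.A_end <= self.model.A0:
            raise ValueError("A_end must exceed the tensionless area A0")
        grid = np.asarray(self.lambda_grid)
        if grid[0] != 0 or grid[-1] != 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("lambda grid must increase strictly from 0 to 1")


#: Shape of the synthetic dV/dlambda profiles.  g'(0) = g'(1) = 0 kills the
#: leading trapezoid error term, so leg integrals hit their targets to
#: O(h^4) on any reasonable grid.  Integral of g over [0,1] is 4/3.
_PROFILE_CURVATURE = 10.0
_PROFILE_INTEGRAL = 1.0 + _PROFILE_CURVATURE / 30.0


def _profile(lam: np.ndarray) -> np.ndarray:
    return 1.0 + _PROFILE_CURVATURE * lam**2 * (1.0 - lam) ** 2


#: Fraction of each state's TI total carried by the van der Waals leg.
_VDW_FRACTION = 0.7


def simulate_dhdl(
    spec: CycleSpec,
    tension_state: str,
    noise: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[LambdaLeg, LambdaLeg]:
    """Synthetic (vdw, coulomb) lambda-legs for one tension state.

    The two legs integrate to dF(state) = dF_solvation (tensionless) or
    dF_solvation + ddF_mechanical (stretched), so the alchemical route
    reproduces the mechanical one by construction.  ``noise`` adds i.i.d.
    Gaussian scatter (kJ/mol) per lambda point and is recorded as the SEM.
    """
    if tension_state not in ("A0", "A"):
        raise ValueError("tension_state must be 'A0' or 'A'")
    ddf, _, _ = closed_form_sensing(spec.model, spec.A_end)
    target = spec.dF_solvation + (ddf if tension_state == "A" else 0.0)
    lam = np.asarray(spec.lambda_grid, dtype=float)
    rng = np.random.default_rng(seed)
    legs = []
    for name, frac in (("vdw", _VDW_FRACTION), ("coulomb", 1.0 - _VDW_FRACTION)):
        mean = target * frac * _profile(lam) / _PROFILE_INTEGRAL
        if noise > 0:
            mean = mean + rng.normal(0.0, noise, size=lam.size)
        legs.append(
            LambdaLeg(
                leg=name,
                lambdas=lam,
                dvdl_mean=mean,
                dvdl_sem=np.full(lam.size, float(noise)),
                tension_state=tension_state,
            )
        )
    return legs[0], legs[1]
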