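"""End-state mechanical free energies of lipid-packing-defect sensing.

A membrane stretched at constant area develops a lateral tension that, for
small relative strains eps = (A - A0)/A0, is Hookean:

    sigma(A) = K_A * eps,

with K_A the area compressibility modulus.  The work of stretching between
two constant-area states follows from the trapezoidal rule,

    dF_s = (sigma(A) + sigma(A0)) / 2 * (A - A0),

and the sensing free energy of a surface-bound peptide is the difference in
stretching work with (primed) and without the peptide:

    ddF_sensing = dF_s' - dF_s
                = (A - A0)/2 * [(sigma'(A) + sigma'(A0)) - (sigma(A) + sigma(A0))].

ddF_sensing < 0 means the peptide senses packing defects (it reduces the
work of stretching the leaflet it adheres to).  Normalizing by the tension
drop of the *peptide-free* reference between the same end states,
dsigma(A) = sigma(A0) - sigma(A), gives the CHAOS parameter
(characteristic area of sensing),

    CHAOS = ddF_sensing / dsigma(A)   [nm^2 per molecule],

which is invariant to the (arbitrary) choice of end states and can be read,
in part, as the leaflet area a bound peptide injects.

Uncertainties are propagated to first order assuming independent tension
estimates (each state is an independent simulation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from . import units
from .tension import TensionEstimate

__all__ = [
    "StretchPoint",
    "StretchCurve",
    "SensingResult",
    "ValueWithError",
    "AreaCompressibilityFit",
    "relative_strain",
    "fit_area_compressibility",
    "stretch_work",
    "stretch_work_multipoint",
    "sensing_free_energy",
    "chaos_parameter",
    "chaos_invariance_profile",
    "HookeanStretchModel",
    "SensingModel",
]

#: Areas closer than this (nm^2) are treated as the same grid point.
AREA_TOL = 1e-6


class ValueWithError(NamedTuple):
    value: float
    error: float


def relative_strain(area: float, area0: float) -> float:
    """Relative area strain eps = (A - A0)/A0 of the tensionless reference."""
    if area0 <= 0:
        raise ValueError("reference area A0 must be positive")
    return (area - area0) / area0


@dataclass
class StretchPoint:
    """One constant-area state on a stretching curve."""

    area: float
    strain: float
    tension: TensionEstimate

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")


@dataclass
class StretchCurve:
    """Tension versus area for one system, anchored at its tensionless area.

    Points are sorted by area; the first point sits at ``area0`` (strain 0).
    ``label`` distinguishes the peptide-free reference from peptide-bound
    systems.
    """

    area0: float
    points: list[StretchPoint]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a stretch curve needs at least two points")
        self.points = sorted(self.points, key=lambda p: p.area)
        areas = self.areas
        if np.any(np.diff(areas) < AREA_TOL):
            raise ValueError("curve areas must be distinct")
        if abs(self.points[0].area - self.area0) > AREA_TOL:
            raise ValueError("first curve point must sit at the reference area A0")
        for p in self.points:
            expected = relative_strain(p.area, self.area0)
            if abs(p.strain - expected) > 1e-9:
                raise ValueError(
                    f"strain {p.strain} inconsistent with area {p.area} and A0 {self.area0}"
                )

    @classmethod
    def from_tensions(
        cls, estimates: Sequence[TensionEstimate], area0: float | None = None, label: str = ""
    ) -> "StretchCurve":
        """Build a curve from tension estimates (areas taken from each estimate)."""
        estimates = sorted(estimates, key=lambda e: e.area)
        if area0 is None:
            area0 = estimates[0].area
        pts = [StretchPoint(e.area, relative_strain(e.area, area0), e) for e in estimates]
        return cls(area0=area0, points=pts, label=label)

    @classmethod
    def from_arrays(
        cls,
        areas: Sequence[float],
        sigmas: Sequence[float],
        sems: Sequence[float] | None = None,
        area0: float | None = None,
        label: str = "",
    ) -> "StretchCurve":
        areas = np.asarray(areas, dtype=float)
        sigmas = np.asarray(sigmas, dtype=float)
        sems = np.zeros_like(sigmas) if sems is None else np.asarray(sems, dtype=float)
        ests = [
            TensionEstimate(
                sigma=float(s), sem=float(e), n_blocks=1, n_frames_used=1,
                t_discard=0.0, area=float(a), label=label,
            )
            for a, s, e in zip(areas, sigmas, sems)
        ]
        return cls.from_tensions(ests, area0=area0, label=label)

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.points])

    @property
    def strains(self) -> np.ndarray:
        return np.array([p.strain for p in self.points])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([p.tension.sigma for p in self.points])

    @property
    def sems(self) -> np.ndarray:
        return np.array([p.tension.sem for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


class AreaCompressibilityFit(NamedTuple):
    """Weighted-least-squares Hookean fit sigma = sigma0 + K_A * eps."""

    k_a: float
    k_a_err: float
    sigma0: float
    residuals: np.ndarray

    def summary(self) -> str:
        lines = [
            "Hookean tension-strain fit",
            "-" * 34,
            f"K_A   {self.k_a:12.4f} +/- {self.k_a_err:.4f} mN/m",
            f"sigma0 {self.sigma0:11.4f} mN/m (anchored)",
            f"rms residual {float(np.sqrt(np.mean(self.residuals ** 2))):.4g} mN/m",
        ]
        return "\n".join(lines)


def fit_area_compressibility(curve: StretchCurve) -> AreaCompressibilityFit:
    """Area compressibility modulus K_A from a stretching curve.

    Fits sigma = sigma(A0) + K_A * eps through the measured anchor point
    (0, sigma(A0)) — only the slope is free.  Points are weighted by
    1/sem^2 when tension SEMs are available, else uniformly.  The slope
    standard error propagates both the per-point SEMs and the anchor
    tension's SEM (the anchor shifts all residuals coherently, and its
    variance usually dominates); unweighted fits with >2 points fall back
    to a residual-based error.
    """
    eps = curve.strains
    if np.allclose(eps, eps[0]):
        raise ValueError("all strains identical; slope undefined")
    sigma0 = curve.sigmas[0]
    sem0 = curve.sems[0]
    dsig = curve.sigmas - sigma0
    mask = np.abs(eps) > 0
    x, y = eps[mask], dsig[mask]
    sems = curve.sems[mask]
    if np.all(sems > 0):
        w = 1.0 / sems**2
        sxx = np.sum(w * x * x)
        k = float(np.sum(w * x * y) / sxx)
        k_err = float(np.sqrt(1.0 / sxx + (sem0 * np.sum(w * x) / sxx) ** 2))
    else:
        k = float(np.sum(x * y) / np.sum(x * x))
        if x.size > 1:
            resid = y - k * x
            s2 = float(np.sum(resid**2) / (x.size - 1))
            k_err = float(np.sqrt(s2 / np.sum(x * x)))
        else:
            k_err = 0.0
    residuals = dsig - k * eps
    return AreaCompressibilityFit(k_a=k, k_a_err=k_err, sigma0=float(sigma0), residuals=residuals)


def stretch_work(
    sigma_a0: TensionEstimate,
    sigma_a: TensionEstimate,
    area0: float,
    area: float,
) -> ValueWithError:
    """Trapezoidal stretching work between two constant-area end states, kJ/mol.

    dF = (sigma(A) + sigma(A0))/2 * (A - A0); antisymmetric under swapping
    the end states.  Error is the quadrature of the two tension SEMs.
    """
    if abs(area - area0) <= AREA_TOL:
        raise ValueError("end states coincide; no stretching work defined")
    da = area - area0
    work_mn = 0.5 * (sigma_a.sigma + sigma_a0.sigma) * da
    err_mn = 0.5 * abs(da) * np.hypot(sigma_a.sem, sigma_a0.sem)
    return ValueWithError(
        units.mech_work_to_kj_per_mol(work_mn),
        units.mech_work_to_kj_per_mol(err_mn),
    )


def _trapezoid_weights(areas: np.ndarray) -> np.ndarray:
    w = np.zeros_like(areas)
    w[0] = 0.5 * (areas[1] - areas[0])
    w[-1] = 0.5 * (areas[-1] - areas[-2])
    if areas.size > 2:
        w[1:-1] = 0.5 * (areas[2:] - areas[:-2])
    return w


def stretch_work_multipoint(curve: StretchCurve) -> ValueWithError:
    """Composite-trapezoid stretching work over all curve points, kJ/mol."""
    areas = curve.areas
    w = _trapezoid_weights(areas)
    work_mn = float(np.sum(w * curve.sigmas))
    err_mn = float(np.sqrt(np.sum((w * curve.sems) ** 2)))
    return ValueWithError(
        units.mech_work_to_kj_per_mol(work_mn),
        units.mech_work_to_kj_per_mol(err_mn),
    )


@dataclass
class SensingResult:
    """Sensing free energy, reference tension drop, and CHAOS for one peptide.

    Sign conventions: ddF < 0 means the peptide is a packing-defect sensor;
    dsigma = sigma(A0) - sigma(A) of the peptide-free reference is negative
    under stretching; CHAOS is then positive for sensors.
    """

    ddF: float
    ddF_err: float
    delta_sigma: float
    chaos: float
    chaos_err: float
    mode: str
    end_states: tuple[float, float]
    label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("end_state", "multi_point"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def is_sensor(self) -> bool:
        return self.ddF < 0

    def to_dict(self) -> dict:
        return {
            "ddF_kJ_per_mol": self.ddF,
            "ddF_err_kJ_per_mol": self.ddF_err,
            "delta_sigma_mN_per_m": self.delta_sigma,
            "chaos_nm2": self.chaos,
            "chaos_err_nm2": self.chaos_err,
            "mode": self.mode,
            "end_states_nm2": list(self.end_states),
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensingResult":
        return cls(
            ddF=d["ddF_kJ_per_mol"],
            ddF_err=d["ddF_err_kJ_per_mol"],
            delta_sigma=d["delta_sigma_mN_per_m"],
            chaos=d["chaos_nm2"],
            chaos_err=d["chaos_err_nm2"],
            mode=d["mode"],
            end_states=tuple(d["end_states_nm2"]),
            label=d.get("label", ""),
        )

    def summary(self) -> str:
        a0, a = self.end_states
        verdict = "sensor (ddF < 0)" if self.is_sensor else "non-sensor"
        lines = [
            f"Packing-defect sensing summary{(' — ' + self.label) if self.label else ''}",
            "=" * 46,
            f"mode             {self.mode}",
            f"end states       A0 = {a0:.3f} nm^2, A = {a:.3f} nm^2",
            f"ddF_sensing      {self.ddF:10.4f} +/- {self.ddF_err:.4f} kJ/mol",
            f"delta_sigma(ref) {self.delta_sigma:10.4f} mN/m",
            f"CHAOS            {self.chaos:10.4f} +/- {self.chaos_err:.4f} nm^2",
            f"verdict          {verdict}",
        ]
        return "\n".join(lines)


def _check_shared_grid(pep: StretchCurve, ref: StretchCurve, full: bool) -> None:
    if abs(pep.area0 - ref.area0) > AREA_TOL:
        raise ValueError("curves have different reference areas A0")
    if full:
        if len(pep) != len(ref) or np.any(np.abs(pep.areas - ref.areas) > AREA_TOL):
            raise ValueError("multi_point mode requires identical area grids")
    else:
        if abs(pep.areas[-1] - ref.areas[-1]) > AREA_TOL:
            raise ValueError("end-state areas differ between the curves")


def sensing_free_energy(
    peptide_curve: StretchCurve,
    reference_curve: StretchCurve,
    mode: str = "end_state",
) -> SensingResult:
    """Sensing free energy ddF = dF_s' - dF_s and its CHAOS parameter.

    ``end_state`` uses only the tensionless and maximally stretched states
    (four tensions); ``multi_point`` integrates the full tension difference
    over the shared area grid with the composite trapezoid.
    """
    if mode == "end_state":
        _check_shared_grid(peptide_curve, reference_curve, full=False)
        p0, pA = peptide_curve.points[0], peptide_curve.points[-1]
        r0, rA = reference_curve.points[0], reference_curve.points[-1]
        da = pA.area - p0.area
        ddf_mn = 0.5 * da * (
            (pA.tension.sigma + p0.tension.sigma) - (rA.tension.sigma + r0.tension.sigma)
        )
        err_mn = 0.5 * abs(da) * np.sqrt(
            pA.tension.sem**2 + p0.tension.sem**2 + rA.tension.sem**2 + r0.tension.sem**2
        )
        ddf = units.mech_work_to_kj_per_mol(ddf_mn)
        err = units.mech_work_to_kj_per_mol(err_mn)
    elif mode == "multi_point":
        _check_shared_grid(peptide_curve, reference_curve, full=True)
        w = _trapezoid_weights(peptide_curve.areas)
        diff = peptide_curve.sigmas - reference_curve.sigmas
        ddf = units.mech_work_to_kj_per_mol(float(np.sum(w * diff)))
        err = units.mech_work_to_kj_per_mol(
            float(np.sqrt(np.sum((w**2) * (peptide_curve.sems**2 + reference_curve.sems**2))))
        )
        r0, rA = reference_curve.points[0], reference_curve.points[-1]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    delta_sigma = r0.tension.sigma - rA.tension.sigma
    chaos, chaos_err = _chaos_from_parts(ddf, err, r0.tension, rA.tension)
    return SensingResult(
        ddF=ddf,
        ddF_err=err,
        delta_sigma=delta_sigma,
        chaos=chaos,
        chaos_err=chaos_err,
        mode=mode,
        end_states=(reference_curve.points[0].area, reference_curve.points[-1].area),
        label=peptide_curve.label,
    )


def _chaos_from_parts(
    ddf: float,
    ddf_err: float,
    sigma_ref_a0: TensionEstimate,
    sigma_ref_a: TensionEstimate,
) -> tuple[float, float]:
    delta_sigma = sigma_ref_a0.sigma - sigma_ref_a.sigma
    if delta_sigma == 0:
        raise ZeroDivisionError(
            "reference tensions are equal between the end states; CHAOS undefined"
        )
    denom = units.tension_to_energy_density(delta_sigma)  # kJ/mol/nm^2
    denom_err = units.tension_to_energy_density(
        float(np.hypot(sigma_ref_a0.sem, sigma_ref_a.sem))
    )
    chaos = ddf / denom
    if ddf != 0:
        rel = np.sqrt((ddf_err / ddf) ** 2 + (denom_err / denom) ** 2)
        chaos_err = abs(chaos) * float(rel)
    else:
        chaos_err = abs(ddf_err / denom)
    return float(chaos), float(chaos_err)


def chaos_parameter(
    result: SensingResult,
    sigma_ref_a0: TensionEstimate,
    sigma_ref_a: TensionEstimate,
) -> ValueWithError:
    """CHAOS = ddF_sensing / dsigma, in nm^2 per molecule.

    ``sigma_ref_a0`` and ``sigma_ref_a`` are the peptide-free reference
    tensions at the two end states (chosen for their small sampling error).
    """
    chaos, err = _chaos_from_parts(result.ddF, result.ddF_err, sigma_ref_a0, sigma_ref_a)
    return ValueWithError(chaos, err)


@dataclass
class ChaosProfilePoint:
    delta_sigma: float
    chaos: float
    chaos_err: float
    end_area: float


def chaos_invariance_profile(
    peptide_curve: StretchCurve,
    reference_curve: StretchCurve,
) -> tuple[list[ChaosProfilePoint], float]:
    """CHAOS recomputed for every available end-state choice (A0, A_i).

    Returns the per-end-state profile and the maximum relative spread
    around the profile mean — near zero when the curves are Hookean with a
    pure area shift, the end-state-invariance property.
    """
    _check_shared_grid(peptide_curve, reference_curve, full=True)
    profile: list[ChaosProfilePoint] = []
    for i in range(1, len(reference_curve)):
        pep_sub = StretchCurve(
            area0=peptide_curve.area0,
            points=[peptide_curve.points[0], peptide_curve.points[i]],
            label=peptide_curve.label,
        )
        ref_sub = StretchCurve(
            area0=reference_curve.area0,
            points=[reference_curve.points[0], reference_curve.points[i]],
            label=reference_curve.label,
        )
        res = sensing_free_energy(pep_sub, ref_sub, mode="end_state")
        profile.append(
            ChaosProfilePoint(
                delta_sigma=res.delta_sigma,
                chaos=res.chaos,
                chaos_err=res.chaos_err,
                end_area=reference_curve.points[i].area,
            )
        )
    values = np.array([p.chaos for p in profile])
    mean = values.mean()
    spread = float(np.max(np.abs(values - mean)) / abs(mean)) if mean != 0 else 0.0
    return profile, spread


class HookeanStretchModel:
    """Model object for the Hookean tension-strain law of one stretch curve.

    ``fit()`` returns an :class:`AreaCompressibilityFit` carrying K_A and
    its standard error.
    """

    def __init__(self, curve: StretchCurve):
        self.curve = curve

    def fit(self) -> AreaCompressibilityFit:
        return fit_area_compressibility(self.curve)


class SensingModel:
    """Model object pairing a peptide-bound curve with its peptide-free
    reference; ``fit`` evaluates the end-state (or multi-point) estimator
    and returns a :class:`SensingResult`."""

    def __init__(self, reference_curve: StretchCurve, peptide_curve: StretchCurve):
        self.reference_curve = reference_curve
        self.peptide_curve = peptide_curve

    def fit(self, mode: str = "end_state") -> SensingResult:
        return sensing_free_energy(self.peptide_curve, self.reference_curve, mode=mode)

    def chaos_profile(self) -> tuple[list[ChaosProfilePoint], float]:
        return chaos_invariance_profile(self.peptide_curve, self.reference_curve)

    def plot(self, ax=None):
        from .plotting import plot_stretch_curves

        return plot_stretch_curves(self.reference_curve, self.peptide_curve, ax=ax)
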