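"""Mappings between leaflet strain, membrane curvature and vesicle size.

A buckled bilayer is cylindrical (curved along x only), so the mean
curvature of the vesicle it emulates is half the cylindrical curvature.
The equivalent vesicle for a flat stretched membrane follows a thin-shell
picture: stretching the outer leaflet of a vesicle of radius R by moving it
a distance d off the midplane gives a relative strain eps ~ 2*d/R, which is
inverted here to estimate R from the applied strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import splev, splrep

__all__ = [
    "BucklePlane",
    "CurvatureProfile",
    "curvature_to_radius",
    "radius_to_curvature",
    "cylindrical_to_mean_curvature",
    "strain_to_vesicle_radius",
    "vesicle_radius_to_strain",
    "buckle_curvature_profile",
    "curvature_finite_difference",
]

#: Default distance (nm) from the bilayer midplane to one leaflet's neutral
#: plane, calibrated so that 16.5% strain maps to a 25 nm diameter vesicle.
DEFAULT_LEAFLET_OFFSET = 1.03


def curvature_to_radius(kappa: float) -> float:
    """Radius R = 1/kappa (nm) of the sphere/cylinder with curvature kappa."""
    if kappa <= 0:
        raise ValueError("curvature must be positive for a finite radius")
    return 1.0 / kappa


def radius_to_curvature(radius: float) -> float:
    """Curvature 1/R (nm^-1); inverse of :func:`curvature_to_radius`."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return 1.0 / radius


def cylindrical_to_mean_curvature(kappa_cyl: float) -> float:
    """Halve a cylindrical curvature to the mean curvature of a sphere.

    A buckle bends in one dimension only; a vesicle of equal mean curvature
    bends in two, so kappa_mean = kappa_cyl / 2.
    """
    return kappa_cyl / 2.0


def strain_to_vesicle_radius(epsilon: float, d_offset: float = DEFAULT_LEAFLET_OFFSET) -> float:
    """Vesicle radius (nm) whose outer leaflet carries strain ``epsilon``.

    Thin-shell mapping eps = 2*d/R solved for R, with ``d_offset`` the
    midplane-to-neutral-plane distance of one leaflet (nm).  A flat
    membrane (eps <= 0) has no finite equivalent vesicle.
    """
    if epsilon <= 0:
        raise ValueError("strain must be positive; a flat membrane has no finite vesicle radius")
    if d_offset <= 0:
        raise ValueError("leaflet offset must be positive")
    return 2.0 * d_offset / epsilon


def vesicle_radius_to_strain(radius: float, d_offset: float = DEFAULT_LEAFLET_OFFSET) -> float:
    """Outer-leaflet strain of a vesicle of radius ``radius`` (inverse map)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if d_offset <= 0:
        raise ValueError("leaflet offset must be positive")
    return 2.0 * d_offset / radius


@dataclass
class BucklePlane:
    """Neutral-plane height profile z(x) of a buckled membrane.

    ``periodic`` marks profiles spanning one full periodic cell of length
    ``cell_length`` (defaults to the x range plus one median spacing).
    """

    x: np.ndarray
    z: np.ndarray
    periodic: bool = True
    cell_length: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.x.size < 8:
            raise ValueError("need at least 8 points to define a buckle shape")
        if self.x.size != self.z.size:
            raise ValueError("x and z must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing within one period")
        if self.periodic and self.cell_length is None:
            dx = float(np.median(np.diff(self.x)))
            self.cell_length = float(self.x[-1] - self.x[0]) + dx


@dataclass
class CurvatureProfile:
    """Signed cylindrical curvature kappa(x) along the buckle."""

    x: np.ndarray
    kappa: np.ndarray


def _spline_derivatives(plane: BucklePlane, smoothing: float) -> tuple[np.ndarray, np.ndarray]:
    if plane.periodic:
        # close the period explicitly for FITPACK's periodic spline
        x = np.append(plane.x, plane.x[0] + plane.cell_length)
        z = np.append(plane.z, plane.z[0])
        tck = splrep(x, z, s=smoothing, per=1)
    else:
        tck = splrep(plane.x, plane.z, s=smoothing)
    zp = np.asarray(splev(plane.x, tck, der=1))
    zpp = np.asarray(splev(plane.x, tck, der=2))
    return zp, zpp


def buckle_curvature_profile(plane: BucklePlane, smoothing: float = 0.0) -> CurvatureProfile:
    """Curvature kappa(x) = z'' / (1 + z'^2)^(3/2) of the neutral plane.

    Derivatives come from a (periodic, when flagged) smoothing-spline fit;
    ``smoothing`` is FITPACK's residual-sum target (0 interpolates).  The
    sign follows z: crests of the peptide-bearing (upper) leaflet have
    negative z'' and hence kappa < 0 convex upward; callers interested only
    in magnitudes can take abs().
    """
    zp, zpp = _spline_derivatives(plane, smoothing)
    kappa = zpp / (1.0 + zp**2) ** 1.5
    return CurvatureProfile(x=plane.x.copy(), kappa=kappa)


def curvature_finite_difference(plane: BucklePlane) -> CurvatureProfile:
    """Cross-check curvature from centered finite differences (no smoothing).

    Noisier than the spline route; intended for validating the spline
    result on clean profiles, not for raw simulation data.
    """
    zp = np.gradient(plane.z, plane.x)
    zpp = np.gradient(zp, plane.x)
    kappa = zpp / (1.0 + zp**2) ** 1.5
    return CurvatureProfile(x=plane.x.copy(), kappa=kappa)
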