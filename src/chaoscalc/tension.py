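"""Surface tension from the diagonal pressure tensor of constant-area runs.

The lateral tension of a membrane spanning the xy plane of a periodic box is

    sigma(t) = L_z(t) * ( P_zz(t) - (P_xx(t) + P_yy(t)) / 2 )

in bar*nm (0.1 mN/m per bar*nm).  Estimates are block-averaged: the
production trace is trimmed for equilibration, split into contiguous blocks,
and the standard error is taken over block means — a simple, reproducible
error model for correlated molecular-dynamics time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import units

__all__ = [
    "PressureTrace",
    "TensionSeries",
    "TensionEstimate",
    "BindingTrace",
    "surface_tension_series",
    "equilibration_trim",
    "block_average",
    "estimate_tension",
    "combine_replicas",
    "binding_trace",
]


@dataclass
class PressureTrace:
    """Per-frame diagonal pressures plus box geometry of a constant-area run.

    Parameters
    ----------
    time : array, ps
    pxx, pyy, pzz : array, bar
    lz : float or array, nm
        Box height; scalar values are broadcast to all frames.
    area : float, nm^2
        The (constant) box area of the run.
    label : str
        Free-text system label (e.g. peptide name or "reference").
    surften : array or None, bar*nm
        Optional precomputed tension column (GROMACS ``#Surf*SurfTen``).
    """

    time: np.ndarray
    pxx: np.ndarray
    pyy: np.ndarray
    pzz: np.ndarray
    lz: np.ndarray
    area: float
    label: str = ""
    surften: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.size
        if n < 1:
            raise ValueError("pressure trace needs at least one frame")
        for name in ("pxx", "pyy", "pzz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != n:
                raise ValueError(f"{name} length {arr.size} != time length {n}")
            setattr(self, name, arr)
        lz = np.broadcast_to(np.asarray(self.lz, dtype=float), (n,)).copy()
        if np.any(lz <= 0):
            raise ValueError("box height Lz must be positive")
        self.lz = lz
        if self.area <= 0:
            raise ValueError("box area must be positive")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.surften is not None:
            st = np.asarray(self.surften, dtype=float)
            if st.size != n:
                raise ValueError("surften column length mismatch")
            self.surften = st

    @property
    def n_frames(self) -> int:
        return self.time.size


@dataclass
class TensionSeries:
    """Per-frame surface tension of one run, in both native unit systems."""

    time: np.ndarray
    bar_nm: np.ndarray

    @property
    def mn_per_m(self) -> np.ndarray:
        return units.bar_nm_to_mn_per_m(self.bar_nm)

    @property
    def n_frames(self) -> int:
        return self.time.size


@dataclass
class TensionEstimate:
    """Block-averaged surface tension at one fixed membrane area.

    ``sigma`` and ``sem`` are in mN/m; ``sem`` is zero for a single block
    (no spread can be estimated) and for noiseless input.
    """

    sigma: float
    sem: float
    n_blocks: int
    n_frames_used: int
    t_discard: float
    area: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be non-negative")
        if self.n_blocks < 1:
            raise ValueError("need at least one block")
        if self.n_frames_used < self.n_blocks:
            raise ValueError("fewer frames than blocks")

    def to_dict(self) -> dict:
        return {
            "sigma_mN_per_m": self.sigma,
            "sem_mN_per_m": self.sem,
            "n_blocks": self.n_blocks,
            "n_frames_used": self.n_frames_used,
            "t_discard_ps": self.t_discard,
            "area_nm2": self.area,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TensionEstimate":
        return cls(
            sigma=d["sigma_mN_per_m"],
            sem=d["sem_mN_per_m"],
            n_blocks=d["n_blocks"],
            n_frames_used=d["n_frames_used"],
            t_discard=d["t_discard_ps"],
            area=d["area_nm2"],
            label=d.get("label", ""),
        )


def surface_tension_series(trace: PressureTrace, source: str = "recompute") -> TensionSeries:
    """Per-frame surface tension from the pressure tensor.

    ``source="recompute"`` evaluates L_z*(P_zz - (P_xx+P_yy)/2) per frame
    (product inside the time average); ``source="surften_column"`` passes
    through a precomputed column when the trace carries one.
    """
    if source == "surften_column":
        if trace.surften is None:
            raise ValueError("trace has no surften column")
        return TensionSeries(time=trace.time, bar_nm=trace.surften.copy())
    if source != "recompute":
        raise ValueError(f"unknown tension source {source!r}")
    sigma = trace.lz * (trace.pzz - 0.5 * (trace.pxx + trace.pyy))
    return TensionSeries(time=trace.time, bar_nm=sigma)


def equilibration_trim(series, t_discard: float):
    """Drop frames with time < ``t_discard`` (ps) for equilibration.

    Works on any object with a ``time`` attribute and per-frame arrays
    (TensionSeries or PressureTrace); the frame exactly at ``t_discard``
    is kept.
    """
    if t_discard < 0:
        raise ValueError("t_discard must be non-negative")
    keep = series.time >= t_discard
    if not np.any(keep):
        raise ValueError(
            f"discarding the first {t_discard} ps leaves no frames "
            f"(trace ends at {series.time[-1]} ps)"
        )
    if isinstance(series, TensionSeries):
        return TensionSeries(time=series.time[keep], bar_nm=series.bar_nm[keep])
    if isinstance(series, PressureTrace):
        return replace(
            series,
            time=series.time[keep],
            pxx=series.pxx[keep],
            pyy=series.pyy[keep],
            pzz=series.pzz[keep],
            lz=series.lz[keep],
            surften=None if series.surften is None else series.surften[keep],
        )
    raise TypeError(f"cannot trim object of type {type(series).__name__}")


def block_average(values: Sequence[float], n_blocks: int) -> tuple[float, float]:
    """Mean and standard error from contiguous block averaging.

    The series is split into ``n_blocks`` equal-length contiguous blocks;
    remainder frames are dropped from the front (the least-equilibrated
    end).  The SEM is the ddof=1 standard deviation of the block means over
    sqrt(n_blocks); it is defined as 0 for a single block.
    """
    values = np.asarray(values, dtype=float)
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if values.size < n_blocks:
        raise ValueError(f"series of length {values.size} shorter than {n_blocks} blocks")
    block_len = values.size // n_blocks
    trimmed = values[values.size - n_blocks * block_len:]
    block_means = trimmed.reshape(n_blocks, block_len).mean(axis=1)
    mean = float(block_means.mean())
    if n_blocks == 1:
        return mean, 0.0
    sem = float(block_means.std(ddof=1) / np.sqrt(n_blocks))
    return mean, sem


def estimate_tension(
    trace: PressureTrace,
    t_discard: float = 0.0,
    n_blocks: int = 5,
    source: str = "recompute",
) -> TensionEstimate:
    """Trim -> per-frame tension -> block average, with provenance fields."""
    series = surface_tension_series(trace, source=source)
    series = equilibration_trim(series, t_discard)
    mean_bar_nm, sem_bar_nm = block_average(series.bar_nm, n_blocks)
    return TensionEstimate(
        sigma=units.bar_nm_to_mn_per_m(mean_bar_nm),
        sem=units.bar_nm_to_mn_per_m(sem_bar_nm),
        n_blocks=n_blocks,
        n_frames_used=series.n_frames,
        t_discard=t_discard,
        area=trace.area,
        label=trace.label,
    )


def combine_replicas(estimates: Sequence[TensionEstimate]) -> TensionEstimate:
    """Replica-based tension estimate: mean and SEM over independent runs.

    Offered alongside block averaging when several traces of the same
    system are available; the replica SEM supersedes the per-run block SEMs.
    """
    if len(estimates) < 2:
        raise ValueError("need at least two replicas")
    areas = {round(e.area, 9) for e in estimates}
    if len(areas) > 1:
        raise ValueError("replicas measured at different areas")
    sigmas = np.array([e.sigma for e in estimates])
    return TensionEstimate(
        sigma=float(sigmas.mean()),
        sem=float(sigmas.std(ddof=1) / np.sqrt(len(sigmas))),
        n_blocks=len(estimates),
        n_frames_used=sum(e.n_frames_used for e in estimates),
        t_discard=estimates[0].t_discard,
        area=estimates[0].area,
        label=estimates[0].label,
    )


@dataclass
class BindingTrace:
    """Moving-averaged peptide-membrane distance with a bound-state summary.

    ``fraction_bound`` is the fraction of raw frames with |z| below the
    threshold; the {bound, partial, unbound} label uses 0.9/0.5 cutoffs on
    that fraction (a package convention, not a literature-standard one).
    """

    time: np.ndarray
    abs_z: np.ndarray
    window: float
    threshold: float
    fraction_bound: float
    classification: str = field(init=False)

    def __post_init__(self) -> None:
        if self.fraction_bound >= 0.9:
            self.classification = "bound"
        elif self.fraction_bound >= 0.5:
            self.classification = "partial"
        else:
            self.classification = "unbound"


def binding_trace(
    time: Sequence[float],
    z: Sequence[float],
    window: float = 100_000.0,
    threshold: float = 1.5,
) -> BindingTrace:
    """Absolute peptide-membrane distance, moving-averaged over ``window`` ps.

    The absolute value is applied per frame *before* averaging, so periodic
    boundary crossings (sign flips of z) do not cancel.  The centered moving
    average uses a window of ``window`` ps (default 100 ns) and returns the
    valid (fully covered) part of the trace.  ``threshold`` (nm, default
    1.5 — the typical initial placement distance) defines the bound state
    on the raw per-frame |z|.
    """
    time = np.asarray(time, dtype=float)
    z = np.asarray(z, dtype=float)
    if window <= 0:
        raise ValueError("window must be positive")
    if time.size != z.size or time.size < 1:
        raise ValueError("time and z must be equal-length, non-empty")
    abs_z = np.abs(z)
    if time.size == 1:
        w = 1
    else:
        dt = float(np.median(np.diff(time)))
        w = max(1, int(round(window / dt)))
        if w > time.size:
            raise ValueError(
                f"window {window} ps exceeds the trace span "
                f"({time.size} frames every {dt} ps)"
            )
    kernel = np.full(w, 1.0 / w)
    smoothed = np.convolve(abs_z, kernel, mode="valid")
    t_smoothed = np.convolve(time, kernel, mode="valid")
    fraction = float(np.mean(abs_z < threshold))
    return BindingTrace(
        time=t_smoothed,
        abs_z=smoothed,
        window=window,
        threshold=threshold,
        fraction_bound=fraction,
    )
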