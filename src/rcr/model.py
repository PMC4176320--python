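"""Closed-form kinetics of template switching in rolling circle amplification.

A strand-displacing polymerase (phi29) on a nicked circular template spools
off a single-stranded concatamer.  At a random, exponentially distributed
time the polymerase switches from the circle onto the displaced strand and
fills it in to double-stranded form; when the fill-in catches up with the
point of initiation the polymerase falls off and the template is dead.

With switching hazard ``lam`` (events s^-1 template^-1), initial template
concentration ``n0`` and per-template elongation rate ``phi`` (mass units
s^-1), the population masses of single- and double-stranded product admit
closed forms in terms of the single identifiable amplitude ``A = 2*n0*phi``::

    N_ds(t) = (A/lam) * (1 - exp(-lam*t/2))**2
    N_ss(t) = (A/lam) * exp(-lam*t/2) * (1 - exp(-lam*t/2))
    N_tot(t) = N_ss + N_ds = (A/lam) * (1 - exp(-lam*t/2))

ssDNA rises to a peak at ``t = 2*ln(2)/lam`` and decays to zero; dsDNA
saturates at the termination plateau ``A/lam``.  All times are seconds and
rates per second; mass units are arbitrary (gel intensity or ng/ul), the
amplitude carries the scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "TimeSeries",
    "switched_fraction",
    "dsdna_rate",
    "mass_ds",
    "mass_ss",
    "mass_total",
    "half_life",
    "ss_peak_time",
    "predict",
]

# below this value of lam*t the expm1-based forms are already exact to
# double precision, but lam == 0 itself needs the analytic limit
_REL_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Kinetic parameters of the switching model.

    Parameters
    ----------
    lam : float
        Switching rate constant, events per second per template.  ``lam = 0``
        means switching never happens (the SSB-saturated limit) and all
        closed forms take their analytic limits.
    amplitude : float
        Combined production-rate constant ``A = 2*n0*phi`` in mass units per
        second.  Only this product is identifiable from mass data.
    n0, phi : float, optional
        Initial template concentration and polymerase elongation rate.
        Metadata: if both are given they must satisfy
        ``amplitude == 2*n0*phi``.
    """

    lam: float
    amplitude: float
    n0: float | None = None
    phi: float | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"switching rate lam must be >= 0, got {self.lam}")
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if self.n0 is not None and self.phi is not None:
            expected = 2.0 * self.n0 * self.phi
            if not math.isclose(self.amplitude, expected, rel_tol=_REL_TOL):
                raise ValueError(
                    f"amplitude={self.amplitude} inconsistent with "
                    f"2*n0*phi={expected}"
                )

    @classmethod
    def from_n0_phi(cls, lam: float, n0: float, phi: float) -> "ModelParams":
        """Construct from template concentration and elongation rate."""
        return cls(lam=lam, amplitude=2.0 * n0 * phi, n0=n0, phi=phi)

    @property
    def plateau(self) -> float:
        """Terminal total-mass plateau A/lam (inf when lam == 0)."""
        return self.amplitude / self.lam if self.lam > 0 else math.inf

    def to_json(self) -> str:
        return json.dumps({"lambda_per_s": self.lam, "amplitude_per_s": self.amplitude})

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        d = json.loads(s)
        return cls(lam=d["lambda_per_s"], amplitude=d["amplitude_per_s"])


@dataclass
class TimeSeries:
    """Paired time points and ss/ds/total mass values.

    ``times`` are seconds, strictly increasing and non-negative; masses are
    non-negative arrays of the same length.  ``total_mass`` defaults to the
    elementwise sum.
    """

    times: np.ndarray
    ss_mass: np.ndarray
    ds_mass: np.ndarray
    total_mass: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ss_mass = np.asarray(self.ss_mass, dtype=float)
        self.ds_mass = np.asarray(self.ds_mass, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, arr in (("ss_mass", self.ss_mass), ("ds_mass", self.ds_mass)):
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must match times in length")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
        if self.total_mass is None:
            self.total_mass = self.ss_mass + self.ds_mass
        else:
            self.total_mass = np.asarray(self.total_mass, dtype=float)
            if not np.allclose(
                self.total_mass, self.ss_mass + self.ds_mass, rtol=1e-9, atol=1e-12
            ):
                raise ValueError("total_mass must equal ss_mass + ds_mass")

    def __len__(self) -> int:
        return len(self.times)


def _check_time(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def switched_fraction(t, lam: float):
    """Fraction of templates that have switched by time ``t``.

    The switching CDF ``1 - exp(-lam*t)``: the expected proportion of the
    initial template pool whose polymerase has left the circle.
    """
    t = _check_time(t)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    out = -np.expm1(-lam * t)
    return float(out) if out.ndim == 0 else out


def dsdna_rate(t, params: ModelParams):
    """Instantaneous dsDNA production rate, mass units per second.

    Only templates that switched between ``t/2`` and ``t`` are actively
    filling in at time ``t``, so the rate is the amplitude times the
    switching probability mass on that window:
    ``A * (exp(-lam*t/2) - exp(-lam*t))``.
    """
    t = _check_time(t)
    lam = params.lam
    out = params.amplitude * (np.exp(-lam * t / 2.0) - np.exp(-lam * t))
    return float(out) if out.ndim == 0 else out


def mass_ds(t, params: ModelParams):
    """Cumulative dsDNA mass ``(A/lam) * (1 - exp(-lam*t/2))**2``.

    Monotone non-decreasing from 0 to the plateau ``A/lam``.  At ``lam = 0``
    no template ever switches and the value is identically 0.
    """
    t = _check_time(t)
    lam = params.lam
    if lam == 0.0:
        out = np.zeros_like(t)
    else:
        out = (params.amplitude / lam) * np.expm1(-lam * t / 2.0) ** 2
    return float(out) if out.ndim == 0 else out


def mass_ss(t, params: ModelParams):
    """Cumulative ssDNA mass ``(A/lam) * exp(-lam*t/2) * (1 - exp(-lam*t/2))``.

    Rises from 0, peaks at ``2*ln(2)/lam``, and decays back to 0 as fill-in
    consumes the displaced strands.  At ``lam = 0`` production is pure strand
    displacement: ``A*t/2 = n0*phi*t``.
    """
    t = _check_time(t)
    lam = params.lam
    if lam == 0.0:
        out = params.amplitude * t / 2.0
    else:
        x = -np.expm1(-lam * t / 2.0)  # 1 - exp(-lam t/2), stable for small lam*t
        out = (params.amplitude / lam) * (1.0 - x) * x
    return float(out) if out.ndim == 0 else out


def mass_total(t, params: ModelParams):
    """Total produced mass ``N_ss + N_ds = (A/lam) * (1 - exp(-lam*t/2))``."""
    t = _check_time(t)
    lam = params.lam
    if lam == 0.0:
        out = params.amplitude * t / 2.0
    else:
        out = -(params.amplitude / lam) * np.expm1(-lam * t / 2.0)
    return float(out) if out.ndim == 0 else out


def half_life(lam: float) -> float:
    """Template half-life before switching, ``ln(2)/lam`` seconds."""
    if lam <= 0:
        raise ValueError("lam must be > 0 for a finite half-life")
    return math.log(2.0) / lam


def ss_peak_time(lam: float) -> float:
    """Time of maximal ssDNA mass, ``2*ln(2)/lam`` seconds."""
    if lam <= 0:
        raise ValueError("lam must be > 0 for a finite peak time")
    return 2.0 * math.log(2.0) / lam


def predict(times: Sequence[float], params: ModelParams) -> TimeSeries:
    """Evaluate the closed-form model on a grid of times (seconds)."""
    times = np.asarray(times, dtype=float)
    return TimeSeries(
        times=times,
        ss_mass=np.atleast_1d(mass_ss(times, params)),
        ds_mass=np.atleast_1d(mass_ds(times, params)),
    )
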