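"""Synthetic gel-densitometry time courses for the RCA switching model.

Emulates the two-channel quantification workflow used for real reactions:
total DNA is read off denaturing PAGE bands, dsDNA off native agarose
bands, and ssDNA is obtained by subtracting the second from the first
(then floored at zero, since band intensities cannot be negative).  The
generating truth is either the closed-form model or a stochastic
population simulation; each channel is corrupted independently with
multiplicative lognormal noise (gel intensities scale with signal) plus a
small additive background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import model as _model
from .model import ModelParams
from .simulator import SimConfig, simulate

__all__ = ["NoiseModel", "MeasurementTable", "generate", "DEFAULT_TIMES_H"]

#: default sampling grid, hours — reactions heat-inactivated from 1 to 72 h
DEFAULT_TIMES_H = (1.0, 3.0, 6.0, 9.0, 12.0, 16.0, 20.0, 24.0, 36.0, 48.0, 72.0)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise for band-intensity channels.

    cv_multiplicative : coefficient of variation of the lognormal
        multiplicative factor (mean 1).  Default 0.10, typical of gel
        densitometry.
    sigma_additive : standard deviation of additive background noise, in
        mass units.
    seed : RNG seed.
    """

    cv_multiplicative: float = 0.10
    sigma_additive: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_multiplicative < 0:
            raise ValueError("cv_multiplicative must be >= 0")
        if self.sigma_additive < 0:
            raise ValueError("sigma_additive must be >= 0")

    def corrupt(self, truth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Apply multiplicative-lognormal then additive noise; floor at 0."""
        out = np.asarray(truth, dtype=float).copy()
        if self.cv_multiplicative > 0:
            # lognormal with mean exactly 1 and the requested CV
            s2 = math.log1p(self.cv_multiplicative**2)
            factor = rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=out.shape)
            out = out * factor
        if self.sigma_additive > 0:
            out = out + rng.normal(0.0, self.sigma_additive, size=out.shape)
        return np.maximum(out, 0.0)


@dataclass
class MeasurementTable:
    """Noisy two-channel measurement of an RCA time course.

    ``total_dna`` is the denaturing-PAGE channel (observes ss + ds),
    ``ds_dna`` the native agarose channel (observes ds), and ``ss_dna`` is
    their difference floored at zero — so ``ss_dna + ds_dna`` may exceed
    ``total_dna`` only through that flooring.
    """

    times_h: np.ndarray
    total_dna: np.ndarray
    ds_dna: np.ndarray
    ss_dna: np.ndarray
    truth: ModelParams | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.total_dna = np.asarray(self.total_dna, dtype=float)
        self.ds_dna = np.asarray(self.ds_dna, dtype=float)
        self.ss_dna = np.asarray(self.ss_dna, dtype=float)
        if not (
            self.times_h.shape
            == self.total_dna.shape
            == self.ds_dna.shape
            == self.ss_dna.shape
        ):
            raise ValueError("all columns must have equal length")
        if np.any(self.ss_dna < 0):
            raise ValueError("ss_dna must be non-negative")

    @property
    def times_s(self) -> np.ndarray:
        return self.times_h * 3600.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times_h,
                "total_dna": self.total_dna,
                "ds_dna": self.ds_dna,
                "ss_dna": self.ss_dna,
            }
        )

    def __len__(self) -> int:
        return len(self.times_h)


def generate(
    params: ModelParams,
    times_h: Sequence[float] = DEFAULT_TIMES_H,
    noise: NoiseModel = NoiseModel(),
    mode: Literal["closed_form", "stochastic"] = "closed_form",
    n_templates: int = 10_000,
) -> MeasurementTable:
    """Generate a noisy measurement table from the switching model.

    Parameters
    ----------
    params : ModelParams
        Generating truth (lam, amplitude).  In ``stochastic`` mode the
        per-template rate is ``phi = amplitude / (2 * n_templates)`` so the
        population expectation matches the closed form.
    times_h : sequence of float
        Sampling times in hours, sorted and non-negative.
    noise : NoiseModel
        Channel noise; total and ds channels are corrupted independently.
    mode : {"closed_form", "stochastic"}
        Whether the truth is the deterministic model or one Monte-Carlo
        population realization.
    n_templates : int
        Population size for ``stochastic`` mode.
    """
    times_h = np.asarray(times_h, dtype=float)
    if times_h.size == 0:
        raise ValueError("times_h must be non-empty")
    if np.any(times_h < 0) or np.any(np.diff(times_h) <= 0):
        raise ValueError("times_h must be sorted, strictly increasing, non-negative")
    times_s = times_h * 3600.0

    rng = np.random.default_rng(noise.seed)
    if mode == "closed_form":
        ss_true = np.atleast_1d(_model.mass_ss(times_s, params))
        ds_true = np.atleast_1d(_model.mass_ds(times_s, params))
    elif mode == "stochastic":
        sim = simulate(
            SimConfig(
                n_templates=n_templates,
                lam=params.lam,
                phi=params.amplitude / (2.0 * n_templates),
                query_times=tuple(times_s),
                seed=int(rng.integers(0, 2**31)),
            )
        )
        ss_true, ds_true = sim.ss_mass, sim.ds_mass
    else:
        raise ValueError(f"unknown mode {mode!r}")

    total_obs = noise.corrupt(ss_true + ds_true, rng)
    ds_obs = noise.corrupt(ds_true, rng)
    # subtraction first, flooring second — mirrors the gel quantification
    ss_obs = np.maximum(total_obs - ds_obs, 0.0)
    return MeasurementTable(
        times_h=times_h,
        total_dna=total_obs,
        ds_dna=ds_obs,
        ss_dna=ss_obs,
        truth=params,
    )
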