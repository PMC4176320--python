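"""Levenberg-Marquardt estimation of the switching rate and amplitude.

Replicates the quantification strategy used for the real gel data: the
objective is built from the ssDNA points only (default), and the dsDNA
curve is then *predicted* from the same fitted ``(lam, A)`` pair rather
than fitted independently — agreement of that prediction with withheld
dsDNA observations is the model-adequacy check.

The optimizer works on ``(log lam, log A)`` by default so both parameters
stay positive without constrained solvers, with analytic Jacobians.
Uncertainty is a Jacobian-based asymptotic covariance at the optimum; the
default is the HC3 heteroscedasticity-robust (sandwich) form, because band
intensities carry multiplicative noise and the subtraction-derived ssDNA
channel is strongly heteroscedastic — late time points, where the true
ssDNA signal is near zero, are the noisiest.  The classical homoskedastic
``s^2 (J^T J)^-1`` form is available as an option.  Standard deviations
are computed on the log scale and delta-transformed; confidence intervals
are therefore multiplicative (symmetric in log lam).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Union

import numpy as np
from scipy.optimize import least_squares

from .model import ModelParams, TimeSeries, predict
from .synth import MeasurementTable

__all__ = ["FitConfig", "FitResult", "FitError", "fit", "initial_guess", "predict_with_fit"]

Data = Union[MeasurementTable, TimeSeries]


class FitError(ValueError):
    """Raised for data that cannot support an estimate."""


@dataclass(frozen=True)
class FitConfig:
    """Controls for the least-squares fit.

    channels : "ss_only" fits the ssDNA points only (default, matching the
        densitometry protocol); "joint_ss_ds" stacks ss and ds residuals.
    log_parameterization : optimize over (log lam, log A) to enforce
        positivity.
    init : optional explicit (lam0, A0); otherwise a peak-based heuristic.
    relative_weights : divide residuals by the observed values (floored at
        1% of the maximum) instead of uniform weighting.
    """

    channels: Literal["ss_only", "joint_ss_ds"] = "ss_only"
    log_parameterization: bool = True
    init: tuple | None = None
    relative_weights: bool = False
    uncertainty: Literal["hc3", "homoskedastic"] = "hc3"
    max_iterations: int = 1000
    convergence_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.channels not in ("ss_only", "joint_ss_ds"):
            raise ValueError(f"unknown channels {self.channels!r}")
        if self.uncertainty not in ("hc3", "homoskedastic"):
            raise ValueError(f"unknown uncertainty {self.uncertainty!r}")


@dataclass
class FitResult:
    """Point estimates, uncertainty and diagnostics of an LM fit."""

    lam_hat: float
    amplitude_hat: float
    lam_sd: float
    amplitude_sd: float
    residuals: np.ndarray
    rss: float
    converged: bool
    n_iter: int
    message: str = ""
    config: FitConfig = field(default_factory=FitConfig, repr=False)

    @property
    def params(self) -> ModelParams:
        return ModelParams(lam=self.lam_hat, amplitude=self.amplitude_hat)

    @property
    def half_life_h(self) -> float:
        """Estimated template half-life before switching, hours."""
        return math.log(2.0) / self.lam_hat / 3600.0

    def lam_interval(self, n_sd: float = 2.0) -> tuple[float, float]:
        """Multiplicative +/- ``n_sd`` interval for lam.

        Symmetric in log lam (the scale the fit works on):
        ``lam_hat * exp(-/+ n_sd * sd_log)`` with
        ``sd_log = lam_sd / lam_hat``.
        """
        if not math.isfinite(self.lam_sd):
            return (math.nan, math.nan)
        sd_log = self.lam_sd / self.lam_hat
        return (
            self.lam_hat * math.exp(-n_sd * sd_log),
            self.lam_hat * math.exp(n_sd * sd_log),
        )

    def covers(self, lam: float, n_sd: float = 2.0) -> bool:
        """Whether ``lam`` lies inside the +/- ``n_sd`` interval."""
        lo, hi = self.lam_interval(n_sd)
        return bool(lo <= lam <= hi)

    def to_dict(self) -> dict:
        return {
            "lam_per_s": self.lam_hat,
            "lam_sd_per_s": self.lam_sd,
            "amplitude_per_s": self.amplitude_hat,
            "amplitude_sd_per_s": self.amplitude_sd,
            "half_life_h": self.half_life_h,
            "rss": self.rss,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "message": self.message,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _extract(data: Data) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Times in seconds, ss and ds observations from either container."""
    if isinstance(data, MeasurementTable):
        return data.times_s, data.ss_dna, data.ds_dna
    if isinstance(data, TimeSeries):
        return data.times, data.ss_mass, data.ds_mass
    raise TypeError(f"cannot fit data of type {type(data).__name__}")


def initial_guess(data: Data) -> tuple[float, float]:
    """Peak-based starting point (lam0, A0).

    The ssDNA curve peaks at ``t* = 2 ln2 / lam`` with height ``A/(4 lam)``,
    so the observed peak time inverts to ``lam0`` and the peak height sets
    ``A0``.  If the observed maximum sits on the first or last grid point
    (no interior peak, e.g. the lam ~ 0 regime) the guess falls back to
    ``lam0 = ln2 / median(t)``.
    """
    t, ss, _ = _extract(data)
    if len(t) < 2 or not np.any(ss > 0):
        raise FitError("need at least two time points with a positive ss value")
    ipk = int(np.argmax(ss))
    if 0 < ipk < len(t) - 1 and t[ipk] > 0:
        lam0 = 2.0 * math.log(2.0) / t[ipk]
    else:
        lam0 = math.log(2.0) / float(np.median(t[t > 0]))
    # scale A0 so the model passes through the observed maximum
    u = math.exp(-lam0 * t[ipk] / 2.0)
    shape = max(u * (1.0 - u), 1e-12)
    a0 = float(ss[ipk]) * lam0 / shape
    return lam0, a0


def _model_and_jac(t: np.ndarray, lam: float, amp: float):
    """N_ss, N_ds and their derivatives w.r.t. (log lam, log A)."""
    u = np.exp(-lam * t / 2.0)
    one_minus_u = -np.expm1(-lam * t / 2.0)
    n_ss = (amp / lam) * u * one_minus_u
    n_ds = (amp / lam) * one_minus_u**2
    # d/d(log lam) = lam * d/dlam
    dss_dloglam = -n_ss - (amp * t / 2.0) * u * (1.0 - 2.0 * u)
    dds_dloglam = -n_ds + amp * t * u * one_minus_u
    return n_ss, n_ds, dss_dloglam, dds_dloglam


def fit(data: Data, config: FitConfig = FitConfig()) -> FitResult:
    """Estimate (lam, amplitude) from a measured time series by LM.

    Minimizes the sum of squared ss residuals (or stacked ss+ds residuals
    in joint mode).  Deterministic given data and config.  Non-convergence
    is reported in the result, never silently; degenerate data (fewer than
    3 distinct times, or no positive ss point) raises :class:`FitError`.
    """
    t, ss, ds = _extract(data)
    if len(np.unique(t)) < 3:
        raise FitError("need at least 3 data points with distinct times")
    if not np.any(ss > 0):
        raise FitError("all ss observations are zero; rate is unidentifiable")

    lam0, a0 = config.init if config.init is not None else initial_guess(data)
    if lam0 <= 0 or a0 <= 0:
        raise FitError("initial values must be positive")

    joint = config.channels == "joint_ss_ds"
    if config.relative_weights:
        w_ss = 1.0 / np.maximum(ss, 0.01 * ss.max())
        w_ds = 1.0 / np.maximum(ds, 0.01 * max(ds.max(), 1e-300)) if joint else None
    else:
        w_ss = np.ones_like(ss)
        w_ds = np.ones_like(ds) if joint else None

    log_space = config.log_parameterization

    def unpack(x):
        return (math.exp(x[0]), math.exp(x[1])) if log_space else (x[0], x[1])

    def residuals(x):
        lam, amp = unpack(x)
        n_ss, n_ds, _, _ = _model_and_jac(t, lam, amp)
        r = (n_ss - ss) * w_ss
        if joint:
            r = np.concatenate([r, (n_ds - ds) * w_ds])
        return r

    def jacobian(x):
        lam, amp = unpack(x)
        n_ss, n_ds, dss_dl, dds_dl = _model_and_jac(t, lam, amp)
        j_ss = np.column_stack([dss_dl * w_ss, n_ss * w_ss])
        if joint:
            j_ss = np.vstack([j_ss, np.column_stack([dds_dl * w_ds, n_ds * w_ds])])
        if not log_space:
            # chain rule back from (log lam, log A) to (lam, A)
            j_ss = j_ss / np.array([lam, amp])
        return j_ss

    if log_space:
        x0 = np.array([math.log(lam0), math.log(a0)])
        sol = least_squares(
            residuals,
            x0,
            jac=jacobian,
            method="lm",
            xtol=config.convergence_tol,
            ftol=config.convergence_tol,
            gtol=config.convergence_tol,
            max_nfev=config.max_iterations,
        )
    else:
        sol = least_squares(
            residuals,
            np.array([lam0, a0]),
            jac=jacobian,
            method="trf",
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            xtol=config.convergence_tol,
            ftol=config.convergence_tol,
            gtol=config.convergence_tol,
            max_nfev=config.max_iterations,
        )

    lam_hat, amp_hat = unpack(sol.x)
    rss = float(np.sum(sol.fun**2))
    m, p = sol.fun.size, 2
    lam_sd = amp_sd = math.nan
    if m > p:
        J, r = sol.jac, sol.fun
        try:
            bread = np.linalg.inv(J.T @ J)
            if config.uncertainty == "hc3":
                # leverage-corrected sandwich: robust to the strongly
                # heteroscedastic subtraction-channel noise
                h = np.clip(np.einsum("ij,jk,ik->i", J, bread, J), 0.0, 0.9999)
                rh = r / (1.0 - h)
                cov = bread @ (J.T * rh**2) @ J @ bread
            else:
                cov = (rss / (m - p)) * bread
            if log_space:
                # delta method: sd(theta) = theta * sd(log theta)
                scale = np.array([lam_hat, amp_hat])
            else:
                scale = np.ones(2)
            sds = np.sqrt(np.maximum(np.diag(cov), 0.0)) * scale
            lam_sd, amp_sd = float(sds[0]), float(sds[1])
        except np.linalg.LinAlgError:
            pass

    return FitResult(
        lam_hat=lam_hat,
        amplitude_hat=amp_hat,
        lam_sd=lam_sd,
        amplitude_sd=amp_sd,
        residuals=sol.fun.copy(),
        rss=rss,
        converged=bool(sol.success),
        n_iter=int(sol.nfev),
        message=str(sol.message),
        config=config,
    )


def predict_with_fit(result: FitResult, times) -> TimeSeries:
    """Evaluate both ss and ds curves at ``times`` (seconds) from one fit.

    Both curves come from the single fitted (lam, A) pair; refuses an
    unconverged result.
    """
    if not result.converged:
        raise FitError(
            f"cannot predict from an unconverged fit: {result.message or 'no diagnostic'}"
        )
    return predict(np.asarray(times, dtype=float), result.params)
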