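"""Mono-exponential time-activity kinetics.

Activity-concentration measurements of an organ (from quantitative SPECT) or
of blood (from a well counter) are described by a single decaying exponential

    C(t) = c0 * exp(-lambda_eff * t),

where ``lambda_eff`` combines biological clearance with the physical decay of
177Lu.  The module fits that curve, propagates a first-cycle effective
half-life to later cycles that contribute only one time point, and integrates
the curve to infinity to obtain concentration residence times.

Times are in hours post-injection throughout; the hours-to-seconds conversion
(x3600) happens only when a residence time is formed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, InsufficientDataError, NonPhysicalFitError

__all__ = [
    "LU177_HALF_LIFE_H",
    "LU177_LAMBDA_H",
    "ORGAN_LABELS",
    "TimedSample",
    "MonoExpFit",
    "ResidenceTime",
    "fit_monoexp",
    "rescale_to_cycle",
    "residence_time",
]

#: Physical half-life of 177Lu, hours (6.647 days).
LU177_HALF_LIFE_H = 6.647 * 24.0
#: Physical decay constant of 177Lu, 1/h — a lower bound on any effective
#: decay constant; effective clearance cannot be slower than physical decay.
LU177_LAMBDA_H = math.log(2.0) / LU177_HALF_LIFE_H

#: Recognised sample labels.  ``bone_marrow`` is a dose target, not a sampled
#: tissue: its kinetics are taken from blood.
ORGAN_LABELS = ("kidneys", "liver", "spleen", "remainder", "tumor", "blood")

SAMPLE_SOURCES = ("spect", "blood_counter")


@dataclass(frozen=True)
class TimedSample:
    """One activity-concentration measurement at a time post-injection.

    Parameters
    ----------
    organ
        Tissue label, one of :data:`ORGAN_LABELS`.
    time_h
        Hours post-injection, > 0.
    conc
        Activity concentration, MBq/kg, >= 0.
    cycle
        Treatment cycle (1-based).
    source
        ``"spect"`` for image-derived samples, ``"blood_counter"`` for blood.
    """

    organ: str
    time_h: float
    conc: float
    cycle: int = 1
    source: str = "spect"

    def __post_init__(self) -> None:
        if self.organ not in ORGAN_LABELS:
            raise DomainError(f"unknown organ label {self.organ!r}")
        if self.time_h <= 0:
            raise DomainError(f"time_h must be > 0, got {self.time_h}")
        if self.conc < 0:
            raise DomainError(f"conc must be >= 0, got {self.conc}")
        if self.cycle < 1:
            raise DomainError(f"cycle must be >= 1, got {self.cycle}")
        if self.source not in SAMPLE_SOURCES:
            raise DomainError(f"unknown sample source {self.source!r}")


@dataclass(frozen=True)
class MonoExpFit:
    """Fitted mono-exponential curve for one organ and one cycle.

    ``c0`` is the extrapolated concentration at t=0 in MBq/kg and
    ``lambda_eff`` the effective decay constant in 1/h.
    """

    c0: float
    lambda_eff: float
    n_points: int = 0
    rss: float = 0.0
    organ: str | None = None
    half_life_h: float = field(init=False)

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise DomainError(f"c0 must be > 0, got {self.c0}")
        if self.lambda_eff <= 0:
            raise NonPhysicalFitError(
                f"lambda_eff must be > 0, got {self.lambda_eff}"
            )
        object.__setattr__(self, "half_life_h", math.log(2.0) / self.lambda_eff)

    def conc_at(self, time_h: float) -> float:
        """Concentration predicted by the curve at ``time_h`` hours."""
        return self.c0 * math.exp(-self.lambda_eff * time_h)


@dataclass(frozen=True)
class ResidenceTime:
    """Concentration residence time, (MBq*s)/(MBq*kg), for one organ/cycle."""

    organ: str
    value: float
    cycle: int = 1

    def __post_init__(self) -> None:
        if self.value < 0:
            raise DomainError(f"residence time must be >= 0, got {self.value}")


def _validate_fit_input(samples: list[TimedSample]) -> tuple[np.ndarray, np.ndarray]:
    if len(samples) < 2:
        raise InsufficientDataError(
            f"mono-exponential fit needs >= 2 samples, got {len(samples)}"
        )
    organs = {s.organ for s in samples}
    if len(organs) != 1:
        raise DomainError(f"samples mix organs: {sorted(organs)}")
    t = np.array([s.time_h for s in samples], dtype=float)
    c = np.array([s.conc for s in samples], dtype=float)
    if np.any(c <= 0):
        raise DomainError("all concentrations must be > 0 for fitting")
    if len(np.unique(t)) != len(t):
        raise DomainError("sample times must be distinct")
    return t, c


def fit_monoexp(samples: list[TimedSample]) -> MonoExpFit:
    """Fit C(t) = c0*exp(-lambda*t) to one organ's samples of one cycle.

    With exactly two samples the curve passes through both points (closed
    form, matching the blood fit which has only the 18 h and 25 h draws).
    With three or more, nonlinear least squares is run in linear
    concentration space, initialised from the log-linear ordinary least
    squares solution; fitting in log space alone would bias the estimate
    under multiplicative noise.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 samples.
    DomainError
        Non-positive concentration, repeated times, or mixed organs.
    NonPhysicalFitError
        The best fit rises with time (lambda <= 0).
    """
    t, c = _validate_fit_input(samples)
    organ = samples[0].organ
    order = np.argsort(t)
    t, c = t[order], c[order]

    if len(t) == 2:
        lam = math.log(c[0] / c[1]) / (t[1] - t[0])
        if lam <= 0:
            raise NonPhysicalFitError(
                f"two-point fit gives non-decaying curve (lambda={lam:.4g}/h)"
            )
        c0 = c[0] * math.exp(lam * t[0])
        fit = MonoExpFit(c0=c0, lambda_eff=lam, n_points=2, rss=0.0, organ=organ)
        _warn_if_subphysical(fit)
        return fit

    # log-linear OLS initialiser: ln C = ln c0 - lambda * t
    slope, intercept = np.polyfit(t, np.log(c), 1)
    lam0 = max(-slope, 1e-8)
    c00 = math.exp(intercept)

    def model(tt, c0, lam):
        return c0 * np.exp(-lam * tt)

    popt, _ = curve_fit(model, t, c, p0=(c00, lam0), maxfev=20000)
    c0_hat, lam_hat = float(popt[0]), float(popt[1])
    if lam_hat <= 0 or c0_hat <= 0:
        raise NonPhysicalFitError(
            f"fit gives non-decaying curve (c0={c0_hat:.4g}, lambda={lam_hat:.4g}/h)"
        )
    rss = float(np.sum((model(t, c0_hat, lam_hat) - c) ** 2))
    fit = MonoExpFit(c0=c0_hat, lambda_eff=lam_hat, n_points=len(t), rss=rss,
                     organ=organ)
    _warn_if_subphysical(fit)
    return fit


def _warn_if_subphysical(fit: MonoExpFit) -> None:
    # Noise can push an estimate below the 177Lu physical bound; warn, don't clamp.
    if fit.lambda_eff < LU177_LAMBDA_H:
        warnings.warn(
            f"fitted lambda_eff={fit.lambda_eff:.4g}/h is below the 177Lu "
            f"physical decay constant {LU177_LAMBDA_H:.4g}/h",
            stacklevel=3,
        )


def rescale_to_cycle(reference: MonoExpFit, sample: TimedSample) -> MonoExpFit:
    """Propagate a first-cycle fit to a later cycle with one measurement.

    Later treatment cycles contribute a single time point; assuming an
    unchanged effective half-life between cycles, the curve is re-anchored:
    lambda is kept and c0 = conc * exp(lambda * time_h).
    """
    if sample.conc <= 0:
        raise DomainError(f"sample concentration must be > 0, got {sample.conc}")
    c0 = sample.conc * math.exp(reference.lambda_eff * sample.time_h)
    return MonoExpFit(c0=c0, lambda_eff=reference.lambda_eff, n_points=1,
                      rss=0.0, organ=sample.organ)


def residence_time(fit: MonoExpFit, a_adm: float, *, cycle: int = 1) -> ResidenceTime:
    """Integrate the fitted curve to infinity, per unit administered activity.

    value = integral_0^inf C(t) dt / A_adm = c0 * 3600 / (lambda_eff * A_adm)
    in (MBq*s)/(MBq*kg); the factor 3600 converts the hour-based integral to
    seconds.
    """
    if a_adm <= 0:
        raise DomainError(f"administered activity must be > 0, got {a_adm}")
    value = fit.c0 * 3600.0 / (fit.lambda_eff * a_adm)
    return ResidenceTime(organ=fit.organ or "unknown", value=value, cycle=cycle)
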