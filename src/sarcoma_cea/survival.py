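"""Survival-curve calibration and hazard utilities.

Cancer-related mortality enters the cohort model as a constant (or
Weibull) monthly hazard per (regimen, line).  Published survival curves
are summarised as a handful of (time, survival) anchor points; a line of
best fit through log-survival recovers the hazard by least squares, and
the background (age-related) hazard is netted out under an additive
competing-hazards assumption so that only excess cancer mortality is
applied in progressive-disease states.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .parameters import ParameterError, SecondLineMix

__all__ = [
    "SurvivalPoint",
    "HazardModel",
    "LifeTable",
    "fit_hazard",
    "net_out_background",
    "mixture_hazard",
    "monthly_death_prob",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalPoint:
    """One anchor point on a survival curve: months since line start."""

    time: float
    survival: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be non-negative")
        if not (0.0 < self.survival <= 1.0):
            raise ValueError("survival must lie in (0, 1]")


@dataclass(frozen=True)
class HazardModel:
    """Parametric monthly mortality hazard.

    ``form`` is ``"exponential"`` (constant rate; the default, being the
    minimal straight line through log-survival) or ``"weibull"`` with
    cumulative hazard ``(rate * t) ** shape``.  ``applicability`` records
    what the model describes, e.g. ``("trabectedin", "second")`` or
    ``("background", "-")``.  ``rss`` is the residual sum of squares of
    the calibration fit on the log-survival scale, when fitted.
    """

    rate: float
    shape: float = 1.0
    form: str = "exponential"
    applicability: tuple[str, str] | None = None
    rss: float = 0.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        if self.form not in ("exponential", "weibull"):
            raise ValueError(f"unknown hazard form {self.form!r}")

    def cumulative_hazard(self, t: float) -> float:
        if self.form == "exponential" or self.shape == 1.0:
            return self.rate * t
        return (self.rate * t) ** self.shape

    def survival(self, t: float) -> float:
        return math.exp(-self.cumulative_hazard(t))

    def hazard_at(self, t: float) -> float:
        """Instantaneous hazard; for Weibull, evaluated at time ``t > 0``."""
        if self.form == "exponential" or self.shape == 1.0:
            return self.rate
        if t <= 0:
            return 0.0 if self.shape > 1 else math.inf
        return self.shape * self.rate * (self.rate * t) ** (self.shape - 1.0)


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual all-cause mortality probabilities.

    Converted to a constant monthly hazard within each age year via
    ``h = -ln(1 - q) / 12``.  Ages beyond the table reuse the last entry.
    """

    ages: tuple[int, ...]
    annual_mortality: tuple[float, ...]

    def validate(self) -> None:
        if len(self.ages) != len(self.annual_mortality) or not self.ages:
            raise ParameterError("life table must pair ages with mortality")
        for q in self.annual_mortality:
            if not (0.0 <= q <= 1.0):
                raise ParameterError(f"annual mortality {q} outside [0, 1]")

    def monthly_hazard(self, age: float) -> float:
        idx = min(
            max(int(math.floor(age)) - self.ages[0], 0), len(self.ages) - 1
        )
        q = self.annual_mortality[idx]
        if q >= 1.0:
            return math.inf
        return -math.log1p(-q) / 12.0


def fit_hazard(
    points: Sequence[SurvivalPoint], form: str = "exponential"
) -> HazardModel:
    """Calibrate a hazard model to survival anchor points by least squares.

    The fit is a line of best fit on the log-survival scale.  For the
    exponential form, ``log S(t) = -rate * t`` is fitted through the
    origin, so the slope estimate is ``-sum(t * log S) / sum(t^2)``.  For
    the Weibull form, ``log(-log S) = shape * log(rate) + shape * log t``
    is fitted by ordinary least squares (points with ``S = 1`` carry no
    information and are dropped; at least two informative points with
    distinct times are required).

    Returns the fitted :class:`HazardModel` with the residual sum of
    squares on the fitting scale.
    """
    if len(points) < 2:
        raise ValueError("need at least two survival points")
    times = np.array([p.time for p in points], dtype=float)
    if len(np.unique(times)) != len(times):
        raise ValueError("survival point times must be distinct")
    surv = np.array([p.survival for p in points], dtype=float)
    informative = surv < 1.0
    if form == "exponential":
        t, s = times[informative], surv[informative]
        if t.size == 0:
            raise ValueError("all survival values equal 1; hazard unidentifiable")
        y = np.log(s)
        rate = -float(t @ y) / float(t @ t)
        resid = y + rate * t
        return HazardModel(rate=max(rate, 0.0), rss=float(resid @ resid))
    if form == "weibull":
        keep = informative & (times > 0)
        t, s = times[keep], surv[keep]
        if t.size < 2:
            raise ValueError("Weibull fit needs two informative points")
        x = np.log(t)
        y = np.log(-np.log(s))
        A = np.column_stack([x, np.ones_like(x)])
        (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
        shape = float(slope)
        if shape <= 0:
            raise ValueError("Weibull fit produced non-positive shape")
        rate = float(math.exp(intercept / shape))
        resid = y - A @ np.array([slope, intercept])
        return HazardModel(
            rate=rate, shape=shape, form="weibull", rss=float(resid @ resid)
        )
    raise ValueError(f"unknown hazard form {form!r}")


def net_out_background(total: HazardModel, background_rate: float) -> HazardModel:
    """Remove background mortality from a total-mortality hazard.

    Under additive competing hazards the cancer-specific rate is
    ``total - background``, clamped at zero (with a warning) when the
    fitted total falls below background.
    """
    if background_rate < 0:
        raise ValueError("background hazard must be non-negative")
    cancer = total.rate - background_rate
    if cancer < 0:
        log.warning(
            "total hazard %.4f below background %.4f; clamping cancer hazard to 0",
            total.rate,
            background_rate,
        )
        cancer = 0.0
    return HazardModel(
        rate=cancer,
        shape=total.shape,
        form=total.form,
        applicability=total.applicability,
        rss=total.rss,
    )


def mixture_hazard(
    mix: SecondLineMix, hazards: Mapping[str, float]
) -> float:
    """Probability-weighted average hazard over a second-line mix.

    The cohort reaching second line is distributed across regimens by the
    mix weights, so the aggregate per-cycle cancer hazard is the weighted
    sum of the component rates.
    """
    missing = [name for name in mix.entries if name not in hazards]
    if missing:
        raise ParameterError(f"no hazard for mix component(s) {missing}")
    return float(sum(w * hazards[name] for name, w in mix.entries.items()))


def monthly_death_prob(
    hazard: HazardModel | float, cycle: int = 1, dt: float = 1.0
) -> float:
    """Per-cycle death probability from a hazard over one model cycle.

    For a constant rate ``h`` this is ``1 - exp(-h * dt)``; for a Weibull
    model the cumulative hazard increment over ``(cycle-1, cycle]`` is
    used.
    """
    if isinstance(hazard, HazardModel):
        h1 = hazard.cumulative_hazard(cycle * dt)
        h0 = hazard.cumulative_hazard((cycle - 1) * dt)
        return 1.0 - math.exp(-(h1 - h0))
    if hazard < 0:
        raise ValueError("hazard must be non-negative")
    return 1.0 - math.exp(-hazard * dt)
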