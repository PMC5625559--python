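"""Log-linear dose-response relative-risk functions.

A log-linear dose-response assumes ``ln RR(x) = beta * x``: the relative
risk of disease at daily dose ``x`` (in g/day) relative to zero exposure is
``exp(beta * x)``.  Meta-analyses report an RR at a reference dose (here
100 g/day of meat), which pins down the slope ``beta = ln(RR_ref) / d_ref``.
The "intercept" convention used in comparative risk assessment reports
``-ln(RR_ref)``: the log-risk decline achieved by moving from the reference
dose down to zero exposure, hence negative for harmful exposures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError

__all__ = [
    "RelativeRiskSpec",
    "LogLinearRiskFunction",
    "intercept_from_rr",
    "rescale_rr_dose",
    "fit_loglinear",
    "rr_at_dose",
    "round_half_up",
]

DEFAULT_STEP_G_DAY = 20.0


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    scale = 10.0 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class RelativeRiskSpec:
    """A meta-analytic relative risk with its 95% CI at a stated reference dose.

    Parameters
    ----------
    risk_factor:
        Label for the exposure, e.g. ``"red_meat"`` or ``"processed_meat"``.
    rr_central, rr_lower, rr_upper:
        Central estimate and confidence bounds of the RR, dimensionless.
    reference_dose:
        Dose (g/day) at which the RRs are expressed.
    sex:
        ``"male"``, ``"female"`` or ``"both"`` when the estimate is pooled.
    """

    risk_factor: str
    rr_central: float
    rr_lower: float
    rr_upper: float
    reference_dose: float
    sex: str = "both"

    def __post_init__(self) -> None:
        for name in ("rr_central", "rr_lower", "rr_upper"):
            if getattr(self, name) <= 0:
                raise DomainError(
                    f"{self.risk_factor}: {name} must be positive, "
                    f"got {getattr(self, name)}"
                )
        if not (self.rr_lower <= self.rr_central <= self.rr_upper):
            raise DomainError(
                f"{self.risk_factor}: require rr_lower <= rr_central <= rr_upper, "
                f"got ({self.rr_lower}, {self.rr_central}, {self.rr_upper})"
            )
        if self.reference_dose <= 0:
            raise DomainError(
                f"{self.risk_factor}: reference_dose must be positive, "
                f"got {self.reference_dose}"
            )

    def rr(self, which: str) -> float:
        """Return the RR for a bound name: ``central``, ``lower`` or ``upper``."""
        try:
            return {"central": self.rr_central,
                    "lower": self.rr_lower,
                    "upper": self.rr_upper}[which]
        except KeyError:
            raise DomainError(f"unknown RR bound {which!r}") from None


@dataclass(frozen=True)
class LogLinearRiskFunction:
    """A calibrated log-linear risk function ``RR(x) = exp(beta * x)``.

    ``beta`` has units of 1/(g/day); ``intercept`` equals ``-ln(RR)`` at the
    reference dose; ``step`` is the dose grid unit used when the function is
    combined with a discretized exposure distribution.
    """

    beta: float
    intercept: float
    reference_dose: float
    step: float = DEFAULT_STEP_G_DAY
    risk_factor: str = ""

    def __call__(self, dose: float) -> float:
        return rr_at_dose(self, dose)


def intercept_from_rr(rr: float, risk_factor: str = "") -> float:
    """Return ``-ln(rr)``, the log-risk intercept of the calibration table.

    Negative for RR > 1: moving from the reference dose to zero exposure
    lowers log-risk by ``ln(rr)``.  Full precision is retained; rounding is a
    display concern only.
    """
    if rr <= 0:
        label = f" for {risk_factor}" if risk_factor else ""
        raise DomainError(f"relative risk must be positive{label}, got {rr}")
    return -math.log(rr)


def rescale_rr_dose(rr: float, dose_from: float, dose_to: float) -> float:
    """Re-express an RR stated per ``dose_from`` g/day as an RR per ``dose_to``.

    Under the log-linear model the slope is shared, so
    ``RR_to = RR_from ** (dose_to / dose_from)``.  E.g. an RR of 1.17 per
    50 g/day corresponds to ``1.17 ** 2 = 1.3689`` per 100 g/day.
    """
    if rr <= 0:
        raise DomainError(f"relative risk must be positive, got {rr}")
    if dose_from <= 0 or dose_to <= 0:
        raise DomainError(
            f"doses must be positive, got dose_from={dose_from}, dose_to={dose_to}"
        )
    return rr ** (dose_to / dose_from)


def fit_loglinear(
    spec: RelativeRiskSpec,
    which: str = "central",
    step: float = DEFAULT_STEP_G_DAY,
) -> LogLinearRiskFunction:
    """Calibrate a log-linear risk function to one bound of an RR spec.

    ``beta = ln(rr) / reference_dose`` so that the function reproduces the
    calibrating RR exactly at the reference dose.
    """
    rr = spec.rr(which)
    intercept = intercept_from_rr(rr, spec.risk_factor)
    beta = -intercept / spec.reference_dose
    return LogLinearRiskFunction(
        beta=beta,
        intercept=intercept,
        reference_dose=spec.reference_dose,
        step=step,
        risk_factor=spec.risk_factor,
    )


def rr_at_dose(rf: LogLinearRiskFunction, dose: float) -> float:
    """Evaluate ``RR(dose) = exp(beta * dose)``; RR at dose 0 is exactly 1."""
    if dose < 0:
        raise DomainError(f"dose must be non-negative, got {dose}")
    return math.exp(rf.beta * dose)
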