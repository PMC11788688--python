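"""Linear-quadratic biologically effective dose (BED) computations.

The linear-quadratic (LQ) model summarises a fractionation schedule of
``n`` fractions of ``d`` Gy as a biologically effective dose

    BED = n * d * (1 + d / (alpha/beta)),

with the tissue-specific alpha/beta ratio in Gy (10 Gy is the usual tumour
value for lung, hence the common shorthand BED10).  For hypofractionated
schedules delivered over a non-negligible number of days, intra-treatment
tumour repopulation can be accounted for by subtracting a time factor,
giving the regrowth-corrected BED

    BED_regrowth = BED - (ln 2 / (alpha * T_p)) * Gamma,

where ``alpha`` (1/Gy) is the LQ linear sensitivity, ``T_p`` (days) the
effective tumour doubling time during treatment, and ``Gamma`` (days) the
elapsed treatment time.  The correction never increases BED and vanishes
for a single-day treatment (``Gamma = 0``).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

LN2 = math.log(2.0)

__all__ = [
    "LN2",
    "DoseSchedule",
    "ScheduleValidationError",
    "compute_bed",
    "compute_regrowth_bed",
    "parse_schedule",
    "bed_from_fractions",
    "dose_per_fraction_from_bed",
]


class ScheduleValidationError(ValueError):
    """A dose-schedule field violates its physical constraints.

    Carries the offending field name in :attr:`field` so callers can report
    exactly which quantity was rejected.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


@dataclass(frozen=True)
class DoseSchedule:
    """One fractionation schedule: ``n_fractions`` fractions of
    ``dose_per_fraction_gy`` Gy, delivered over ``elapsed_time_days`` days.

    ``total_dose_gy`` is derived as n*d, so the n*d consistency invariant
    holds by construction.
    """

    n_fractions: int
    dose_per_fraction_gy: float
    elapsed_time_days: float = 0.0
    alpha_beta_gy: float = 10.0

    def __post_init__(self) -> None:
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ScheduleValidationError(
                "n_fractions", f"must be a positive integer, got {self.n_fractions!r}"
            )
        if not (self.dose_per_fraction_gy > 0):
            raise ScheduleValidationError(
                "dose_per_fraction_gy", f"must be > 0 Gy, got {self.dose_per_fraction_gy!r}"
            )
        if not (self.elapsed_time_days >= 0):
            raise ScheduleValidationError(
                "elapsed_time_days", f"must be >= 0 days, got {self.elapsed_time_days!r}"
            )
        if not (self.alpha_beta_gy > 0):
            raise ScheduleValidationError(
                "alpha_beta_gy", f"must be > 0 Gy, got {self.alpha_beta_gy!r}"
            )

    @property
    def total_dose_gy(self) -> float:
        return self.n_fractions * self.dose_per_fraction_gy

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.dose_per_fraction_gy:g} Gy×{self.n_fractions}"


_SCHEDULE_RE = re.compile(
    r"^\s*(?P<dose>\d+(?:\.\d+)?)\s*(?:gy)?\s*[x×\*]\s*(?P<n>\d+)\s*$",
    re.IGNORECASE,
)


def parse_schedule(
    text: str,
    *,
    elapsed_time_days: float = 0.0,
    alpha_beta_gy: float = 10.0,
) -> DoseSchedule:
    """Parse a clinical shorthand such as ``"12.5 Gy×4"`` or ``"12.5x4"``.

    The decimal separator is always a dot, independent of locale.
    """
    m = _SCHEDULE_RE.match(text)
    if m is None:
        raise ScheduleValidationError(
            "schedule", f"cannot parse dose schedule from {text!r} (expected e.g. '12.5 Gy×4')"
        )
    return DoseSchedule(
        n_fractions=int(m.group("n")),
        dose_per_fraction_gy=float(m.group("dose")),
        elapsed_time_days=elapsed_time_days,
        alpha_beta_gy=alpha_beta_gy,
    )


def compute_bed(schedule: DoseSchedule) -> float:
    """Plain LQ biologically effective dose n*d*(1 + d/(alpha/beta)), in Gy."""
    d = schedule.dose_per_fraction_gy
    return schedule.total_dose_gy * (1.0 + d / schedule.alpha_beta_gy)


def compute_regrowth_bed(schedule: DoseSchedule, alpha_per_gy: float, t_p_days: float) -> float:
    """Regrowth-corrected BED: plain BED minus (ln2/(alpha*T_p)) * Gamma.

    ``Gamma`` is the schedule's elapsed treatment time in days; ``t_p_days``
    the effective tumour doubling time during treatment.  Equals
    :func:`compute_bed` exactly when ``Gamma = 0`` and is never larger.
    """
    if not (alpha_per_gy > 0):
        raise ScheduleValidationError("alpha_per_gy", f"must be > 0 /Gy, got {alpha_per_gy!r}")
    if not (t_p_days > 0):
        raise ScheduleValidationError("t_p_days", f"must be > 0 days, got {t_p_days!r}")
    return compute_bed(schedule) - (LN2 / (alpha_per_gy * t_p_days)) * schedule.elapsed_time_days


def bed_from_fractions(n_fractions, dose_per_fraction_gy, alpha_beta_gy: float = 10.0):
    """Vectorised plain BED for arrays of fraction counts and fraction doses."""
    n = np.asarray(n_fractions, dtype=float)
    d = np.asarray(dose_per_fraction_gy, dtype=float)
    return n * d * (1.0 + d / alpha_beta_gy)


def dose_per_fraction_from_bed(bed_gy, n_fractions, alpha_beta_gy: float = 10.0):
    """Invert the LQ relation: the fraction dose d solving n*d*(1+d/ab) = BED.

    Takes the positive root of the quadratic; vectorised.
    """
    bed = np.asarray(bed_gy, dtype=float)
    n = np.asarray(n_fractions, dtype=float)
    ab = float(alpha_beta_gy)
    if np.any(bed < 0):
        raise ScheduleValidationError("bed_gy", "must be >= 0 Gy")
    if np.any(n < 1):
        raise ScheduleValidationError("n_fractions", "must be >= 1")
    return 0.5 * ab * (np.sqrt(1.0 + 4.0 * bed / (n * ab)) - 1.0)
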