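"""Activation-foil beam calibration and pre-treatment QA/QC checks.

Before a treatment the absolute scale of each fission-chamber channel is
anchored by irradiating Au/Cu activation foils: the foil's induced
activity, its decay constant and the per-second corrected counting rates
recorded during the foil irradiation together yield the channel's
reference counting rate CRref at the reference reactor power (1.2 MW).
CRref is the denominator that converts live counting into a fraction of
the planning-reference dose rate.

For a foil irradiated over T one-second ticks with corrected counting
rates CR_t, decay constant lambda (per second) and end-of-irradiation
activity A, the reference rate is

    CRref = (RRref / A) * sum_{t=1..T} CR_t * (1 - exp(-lambda)) * exp(-lambda * (T - t)),

where RRref is the foil's reference (theoretical) reaction rate at the
reference power.  Each tick contributes the activity it induced, decayed
to the end of the irradiation; a constant-rate run at the reference power
therefore returns that rate.

A separate, deliberately simple check records whether the paired
ionization-chamber current sits inside its acceptance band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "FoilIrradiation",
    "QaqcRecord",
    "reference_rate",
    "combined_reference_rate",
    "check_ic_current",
]


@dataclass(frozen=True)
class FoilIrradiation:
    """One activation-foil irradiation record.

    ``cr_series`` holds the per-second corrected counting rates of the
    channel being calibrated, one entry per tick of the ``duration``-second
    irradiation.  ``decay_const`` is the foil decay constant per second;
    ``activity`` the measured end-of-irradiation activity in units
    consistent with ``rr_ref``.
    """

    rr_ref: float
    activity: float
    decay_const: float
    duration: int
    cr_series: tuple[float, ...]
    foil: str = "Au"

    def __post_init__(self) -> None:
        object.__setattr__(self, "cr_series", tuple(float(c) for c in self.cr_series))
        if self.duration < 1:
            raise DomainError("foil irradiation duration must be >= 1 tick")
        if len(self.cr_series) != self.duration:
            raise DomainError(
                f"cr_series has {len(self.cr_series)} entries for duration {self.duration}"
            )
        if not (self.decay_const > 0):
            raise DomainError("decay constant must be positive")
        if self.activity == 0:
            raise ConfigurationError("foil activity is zero: reference rate undefined")
        if not (self.activity > 0):
            raise DomainError("foil activity must be positive")
        if any(c < 0 for c in self.cr_series):
            raise DomainError("counting rates must be non-negative")


def reference_rate(foil: FoilIrradiation) -> float:
    """Reference counting rate CRref of the channel at reference power.

    Strictly positive whenever any tick saw counts; 0 for an all-zero run.
    """
    lam = foil.decay_const
    t = np.arange(1, foil.duration + 1, dtype=float)
    cr = np.asarray(foil.cr_series, dtype=float)
    # (1 - e^-lam) * e^{-lam (T - t)}; underflows cleanly to the final-tick
    # term in the fast-decay limit.
    weights = -np.expm1(-lam) * np.exp(-lam * (foil.duration - t))
    return float(foil.rr_ref / foil.activity * np.dot(cr, weights))


def combined_reference_rate(foils: Iterable[FoilIrradiation]) -> float:
    """Unweighted mean of per-foil CRref values (Au and Cu combined)."""
    rates = [reference_rate(f) for f in foils]
    if not rates:
        raise DomainError("no foil irradiations supplied")
    return float(np.mean(rates))


@dataclass(frozen=True)
class QaqcRecord:
    """One pre-treatment ionization-chamber check."""

    timestamp: str
    ic_current: float
    reference_band: tuple[float, float]
    pass_flag: bool = field(init=False)

    def __post_init__(self) -> None:
        low, high = self.reference_band
        if not (low < high):
            raise DomainError(f"malformed acceptance band {self.reference_band!r}")
        object.__setattr__(self, "pass_flag", low <= self.ic_current <= high)


def check_ic_current(
    current: float,
    band: Sequence[float],
    timestamp: str = "",
    log: list[QaqcRecord] | None = None,
) -> QaqcRecord:
    """Check a paired-ionization-chamber current against its acceptance band.

    Bounds are inclusive.  An out-of-band current is a failed check
    (``pass_flag`` False), not an error.  When ``log`` is given the record
    is appended to it.
    """
    low, high = float(band[0]), float(band[1])
    record = QaqcRecord(timestamp=timestamp, ic_current=float(current), reference_band=(low, high))
    if log is not None:
        log.append(record)
    return record
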