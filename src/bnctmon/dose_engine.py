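"""Per-second boron-weighted prescribed-dose accumulation.

The monitor converts live fission-chamber counting into delivered
biologically weighted dose.  Each one-second tick, with the control
channel's dead-time-corrected counting rate CRcorrect(t) and the
channel's reference rate CRref at the 1.2 MW planning power, contributes

    dD = [ Db10 * BC(t)/BCplan + Dother ] * CRcorrect(t)/CRref * dt

to the running total, where Db10 and Dother are the boron and background
dose rates the treatment-planning system evaluated at reference
conditions (cGy-w/s), BCplan is the boron concentration the plan assumed
and BC(t) the latest measured blood/sample concentration (ppm).  The
counting-rate ratio rescales the planning dose rates to the actual beam
intensity; the concentration ratio rescales only the boron component.

Registration starts on the first tick whose raw control-channel counts
exceed a threshold (default >100 counts per 1-s tick) and is latched, so
the shutdown power tail keeps accumulating.  Concentration measurements
may arrive mid-irradiation: the engine stores the per-tick counting-rate
ratios so the boron component can be re-scaled retroactively, yielding
the "corrected" prescription dose alongside the as-registered one.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import pandas as pd

from . import deadtime
from .deadtime import DeadTimeParams
from .errors import ConfigurationError, DomainError, StateError, StreamError

__all__ = [
    "FieldStatus",
    "TreatmentField",
    "BeamSample",
    "ChannelCalibration",
    "BcTimeline",
    "DoseState",
    "DoseEngine",
    "dose_increment",
    "remaining_time",
    "DOSE_LOG_COLUMNS",
    "TELEMETRY_COLUMNS",
]

TELEMETRY_COLUMNS = ["t_s", "cr_a", "cr_b", "cr_c", "power_mw", "gamma"]
DOSE_LOG_COLUMNS = [
    "t_s",
    "cr_corrected",
    "dose_increment",
    "accumulated",
    "corrected",
    "remaining",
    "remaining_time_s",
]

#: Column of the telemetry CSV carrying each named channel.
CHANNEL_COLUMNS = {"A": "cr_a", "B": "cr_b", "C": "cr_c"}


class FieldStatus:
    """Lifecycle states of a treatment field: open -> irradiation -> final."""

    OPEN = "open"
    IRRADIATION = "irradiation"
    FINAL = "final"

    _ORDER = {OPEN: 0, IRRADIATION: 1, FINAL: 2}

    @classmethod
    def validate_transition(cls, old: str, new: str) -> None:
        if new not in cls._ORDER or old not in cls._ORDER:
            raise StateError(f"unknown field status {old!r} -> {new!r}")
        if cls._ORDER[new] != cls._ORDER[old] + 1:
            raise StateError(f"illegal field status transition {old!r} -> {new!r}")


@dataclass
class TreatmentField:
    """One planning-system field with its prescription parameters.

    Dose rates are cGy-w per second at reference conditions (1.2 MW and
    the planned boron concentration); ``target_dose`` is cGy-w.
    """

    field_id: str
    boron_dose_rate: float
    background_dose_rate: float
    bc_plan: float
    target_dose: float
    status: str = FieldStatus.OPEN

    def __post_init__(self) -> None:
        if self.boron_dose_rate < 0 or self.background_dose_rate < 0:
            raise DomainError("dose rates must be non-negative")
        if not (self.bc_plan > 0):
            raise ConfigurationError("planned boron concentration must be positive")
        if not (self.target_dose > 0):
            raise DomainError("target dose must be positive")

    def advance_status(self, new: str) -> None:
        FieldStatus.validate_transition(self.status, new)
        self.status = new


@dataclass(frozen=True)
class BeamSample:
    """One telemetry tick: per-channel measured rates, power, gamma."""

    t: float
    cr_meas: Mapping[str, float]
    power: float = 0.0
    gamma_dose_rate: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.cr_meas.values()):
            raise DomainError("measured counting rates must be non-negative")
        if self.power < 0:
            raise DomainError("reactor power must be non-negative")


@dataclass(frozen=True)
class ChannelCalibration:
    """Dead-time parameters and reference counting rate for one channel."""

    channel_id: str
    deadtime: DeadTimeParams
    cr_ref: float
    ref_power_mw: float = 1.2

    def __post_init__(self) -> None:
        if self.cr_ref < 0:
            raise DomainError("reference counting rate must be non-negative")


class BcTimeline:
    """Boron-concentration measurements over time, ppm.

    Piecewise-constant, last-value-carried-forward between entries;
    before the first entry the caller-supplied default (normally the
    planned concentration) applies.
    """

    def __init__(self, entries: list[tuple[float, float]] | None = None) -> None:
        self._times: list[float] = []
        self._values: list[float] = []
        for t, v in entries or []:
            self.add(t, v)

    @property
    def entries(self) -> list[tuple[float, float]]:
        return list(zip(self._times, self._values))

    def add(self, t: float, bc_ppm: float) -> None:
        if not (bc_ppm > 0):
            raise DomainError("boron concentration must be positive")
        if self._times and t <= self._times[-1]:
            # allow replacing the value at an existing time; reject reordering
            if t == self._times[-1]:
                self._values[-1] = float(bc_ppm)
                return
            raise DomainError("timeline times must be strictly increasing")
        self._times.append(float(t))
        self._values.append(float(bc_ppm))

    def value_at(self, t: float, default: float) -> float:
        i = bisect.bisect_right(self._times, t)
        if i == 0:
            return default
        return self._values[i - 1]

    def __len__(self) -> int:
        return len(self._times)


@dataclass(frozen=True)
class DoseState:
    """Snapshot of the monitor quantities after a tick."""

    accumulated_dose: float = 0.0
    corrected_dose: float = 0.0
    remaining_dose: float = 0.0
    elapsed_s: float = 0.0
    remaining_time_s: float | None = None
    registering: bool = False
    paused: bool = False
    shutdown: bool = False
    rundown_pct: float = 100.0


def dose_increment(
    sample: BeamSample,
    fld: TreatmentField,
    bc_now: float,
    cal: ChannelCalibration,
    dt: float = 1.0,
) -> float:
    """Dose delivered during one tick, cGy-w.

    ``CRcorrect`` is obtained from the measured rate of the calibration's
    channel via the dead-time inversion.
    """
    if cal.cr_ref == 0:
        raise ConfigurationError(f"channel {cal.channel_id}: cr_ref is zero")
    cr_corr = deadtime.correct(sample.cr_meas[cal.channel_id], cal.deadtime)
    rate = fld.boron_dose_rate * (bc_now / fld.bc_plan) + fld.background_dose_rate
    return rate * (cr_corr / cal.cr_ref) * dt


def remaining_time(remaining_dose: float, total_dose_rate: float) -> float | None:
    """Seconds to completion at the current total dose rate.

    ``None`` flags an undefined estimate (no beam while dose remains).
    """
    if remaining_dose <= 0:
        return 0.0
    if total_dose_rate <= 0:
        return None
    return remaining_dose / total_dose_rate


class DoseEngine:
    """Streaming dose accumulator for one treatment field.

    Feed :class:`BeamSample` ticks through :meth:`step`; the engine keeps
    the telemetry log, the dose log, the registration latch, and the
    per-tick history needed for retroactive concentration re-scaling.
    """

    def __init__(
        self,
        fld: TreatmentField,
        calibrations: Mapping[str, ChannelCalibration],
        bc_timeline: BcTimeline | None = None,
        control_channel: str = "A",
        registration_threshold: float = 100.0,
        rundown_pct: float = 100.0,
        dt: float = 1.0,
        cross_check_tol: float = 0.05,
        warn: Callable[[str], None] | None = None,
    ) -> None:
        if control_channel not in calibrations:
            raise ConfigurationError(f"no calibration for control channel {control_channel!r}")
        if not (0 < rundown_pct <= 100):
            raise ConfigurationError("rundown_pct must lie in (0, 100]")
        if calibrations[control_channel].cr_ref == 0:
            raise ConfigurationError("control-channel cr_ref is zero")
        self.field = fld
        self.calibrations = dict(calibrations)
        self.bc_timeline = bc_timeline if bc_timeline is not None else BcTimeline()
        self.control_channel = control_channel
        self.registration_threshold = float(registration_threshold)
        self.rundown_pct = float(rundown_pct)
        self.dt = float(dt)
        self.cross_check_tol = float(cross_check_tol)
        self._warn = warn
        self.warnings: list[str] = []

        self._last_t: float | None = None
        self._start_t: float | None = None
        self._registering = False
        self._paused = False
        self._shutdown = False
        self._accumulated = 0.0
        self._elapsed = 0.0
        # per registered tick: (t, CRcorrect/CRref on control channel)
        self._hist_t: list[float] = []
        self._hist_ratio: list[float] = []
        self._corrected = 0.0
        self._last_rate = 0.0  # total dose rate on the last registered tick
        self._telemetry_rows: list[dict] = []
        self._dose_rows: list[dict] = []

    # -- state -----------------------------------------------------------

    @property
    def state(self) -> DoseState:
        remaining = max(0.0, self.field.target_dose - self._corrected)
        return DoseState(
            accumulated_dose=self._accumulated,
            corrected_dose=self._corrected,
            remaining_dose=remaining,
            elapsed_s=self._elapsed,
            remaining_time_s=remaining_time(remaining, self._last_rate),
            registering=self._registering,
            paused=self._paused,
            shutdown=self._shutdown,
            rundown_pct=self.rundown_pct,
        )

    @property
    def shutdown_signal(self) -> bool:
        """True once the corrected dose reaches the run-down fraction of target."""
        return self._shutdown

    def _emit_warning(self, msg: str) -> None:
        self.warnings.append(msg)
        if self._warn is not None:
            self._warn(msg)

    # -- streaming -------------------------------------------------------

    def step(self, sample: BeamSample) -> DoseState:
        """Consume one telemetry tick and return the refreshed state."""
        if self._last_t is not None and sample.t <= self._last_t:
            raise StreamError(
                f"out-of-order timestamp {sample.t} after {self._last_t}"
            )
        if self._start_t is None:
            self._start_t = sample.t
        self._last_t = sample.t

        cal = self.calibrations[self.control_channel]
        corrected_rates = {
            ch: deadtime.correct(sample.cr_meas[ch], c.deadtime)
            for ch, c in self.calibrations.items()
            if ch in sample.cr_meas
        }
        cr_corr = corrected_rates[self.control_channel]

        self._telemetry_rows.append(
            {
                "t_s": sample.t,
                **{CHANNEL_COLUMNS.get(ch, f"cr_{ch.lower()}"): sample.cr_meas[ch]
                   for ch in sample.cr_meas},
                "power_mw": sample.power,
                "gamma": sample.gamma_dose_rate,
            }
        )

        inc = 0.0
        if not self._paused:
            counts_in_tick = sample.cr_meas[self.control_channel] * self.dt
            if not self._registering and counts_in_tick > self.registration_threshold:
                self._registering = True
            if self._registering:
                bc_now = self.bc_timeline.value_at(sample.t, default=self.field.bc_plan)
                ratio = cr_corr / cal.cr_ref
                rate = (
                    self.field.boron_dose_rate * (bc_now / self.field.bc_plan)
                    + self.field.background_dose_rate
                )
                inc = rate * ratio * self.dt
                self._accumulated += inc
                self._corrected += inc
                self._elapsed += self.dt
                self._hist_t.append(sample.t)
                self._hist_ratio.append(ratio)
                self._last_rate = rate * ratio
                self._cross_check(corrected_rates)

        if self._corrected >= self.field.target_dose * self.rundown_pct / 100.0:
            self._shutdown = True

        st = self.state
        self._dose_rows.append(
            {
                "t_s": sample.t,
                "cr_corrected": cr_corr,
                "dose_increment": inc,
                "accumulated": st.accumulated_dose,
                "corrected": st.corrected_dose,
                "remaining": st.remaining_dose,
                "remaining_time_s": (
                    math.nan if st.remaining_time_s is None else st.remaining_time_s
                ),
            }
        )
        return st

    def _cross_check(self, corrected_rates: Mapping[str, float]) -> None:
        control = corrected_rates[self.control_channel]
        ref_control = self.calibrations[self.control_channel].cr_ref
        if control <= 0:
            return
        # only meaningful where counting noise is well inside the band:
        # require 3/sqrt(N) < tol over the tick
        if control * self.dt < 9.0 / (self.cross_check_tol * self.cross_check_tol):
            return
        for ch, rate in corrected_rates.items():
            if ch == self.control_channel:
                continue
            ref = self.calibrations[ch].cr_ref
            if ref <= 0:
                continue
            rel = abs(rate / ref - control / ref_control) / (control / ref_control)
            if rel > self.cross_check_tol:
                self._emit_warning(
                    f"t={self._last_t}: channel {ch} disagrees with control "
                    f"{self.control_channel} by {rel:.1%}"
                )

    # -- pause / resume --------------------------------------------------

    def pause(self) -> DoseState:
        if self._paused:
            raise StateError("engine is already paused")
        self._paused = True
        return self.state

    def resume(self) -> DoseState:
        if not self._paused:
            raise StateError("resume without a preceding pause")
        self._paused = False
        return self.state

    # -- dynamic concentration updates -----------------------------------

    def apply_bc_update(self, new_bc: float, at: float) -> DoseState:
        """Record a concentration measurement and re-scale retroactively.

        The boron component of every registered tick at or after ``at`` is
        recomputed with the updated timeline, producing the corrected
        prescription dose; the as-registered accumulated dose is kept
        unchanged alongside it.
        """
        if self._start_t is not None and at < self._start_t:
            raise DomainError(
                f"concentration update at t={at} predates session start t={self._start_t}"
            )
        self.bc_timeline.add(at, new_bc)
        self._recompute_corrected()
        if self._corrected >= self.field.target_dose * self.rundown_pct / 100.0:
            self._shutdown = True
        return self.state

    def _recompute_corrected(self) -> None:
        b = self.field.boron_dose_rate
        o = self.field.background_dose_rate
        bc_plan = self.field.bc_plan
        total = 0.0
        for t, ratio in zip(self._hist_t, self._hist_ratio):
            bc = self.bc_timeline.value_at(t, default=bc_plan)
            total += (b * bc / bc_plan + o) * ratio * self.dt
        self._corrected = total

    # -- exports ---------------------------------------------------------

    def telemetry_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._telemetry_rows, columns=TELEMETRY_COLUMNS)

    def dose_log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._dose_rows, columns=DOSE_LOG_COLUMNS)
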