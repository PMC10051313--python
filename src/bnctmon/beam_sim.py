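"""Synthetic reactor-telemetry generator.

Emulates the operational profile of a research-reactor BNCT irradiation
so every engine path is testable without hardware: a linear power ramp to
operating power (about four minutes by default), a plateau while the
prescribed dose accumulates, and an exponential scram tail when the
reactor is switched off.  Beam-line neutron counting is zero below a
beam-onset power (20 kW by default), Poisson-distributed about the
power-proportional true rate above it, and distorted by the per-channel
dead-time model before it is reported — exactly the raw stream the
monitor must dead-time-correct and normalise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import math

import numpy as np
import pandas as pd

from . import deadtime
from .deadtime import DeadTimeParams
from .dose_engine import (
    BcTimeline,
    BeamSample,
    ChannelCalibration,
    DoseEngine,
    DoseState,
    TreatmentField,
)
from .errors import ConfigurationError

__all__ = ["ScenarioConfig", "SimulationResult", "power_profile", "sample_tick", "run_scenario"]

REFERENCE_POWER_MW = 1.2

#: Default dead-time coefficients: linear channel with a few-percent
#: counting loss at 1e5 counts/s.
DEFAULT_DEADTIME = DeadTimeParams(a_lin=1.0, b_quad=-1e-7)


@dataclass
class ScenarioConfig:
    """Reactor/beam scenario parameters.

    ``gains`` are per-channel true counting rates (counts/s) at the
    1.2 MW reference power; they double as the channels' reference rates
    CRref when no calibration file is supplied.  ``hold_s`` bounds the
    plateau when running for a fixed duration; in target-driven runs the
    plateau ends when the engine raises the shutdown signal.
    """

    operating_power: float = 1.7
    ramp_s: float = 240.0
    hold_s: float = 3600.0
    scram_tau_s: float = 20.0
    beam_onset_power: float = 0.02
    gains: dict[str, float] = dc_field(
        default_factory=lambda: {"A": 1.0e5, "B": 1.0e5, "C": 1.0e5}
    )
    deadtime_params: dict[str, DeadTimeParams] = dc_field(default_factory=dict)
    gamma_coeff: float = 1.0
    gamma_background: float = 0.0
    noise: bool = True
    seed: int = 0
    max_duration_s: float = 4 * 3600.0

    def __post_init__(self) -> None:
        if self.operating_power <= 0 or self.ramp_s < 0 or self.scram_tau_s <= 0:
            raise ConfigurationError("scenario timescales/power must be positive")
        if not (0 <= self.beam_onset_power < self.operating_power):
            raise ConfigurationError("beam onset power must lie below operating power")
        for ch in self.gains:
            self.deadtime_params.setdefault(ch, DEFAULT_DEADTIME)

    def calibrations(self) -> dict[str, ChannelCalibration]:
        """Channel calibrations consistent with this scenario's truth."""
        return {
            ch: ChannelCalibration(
                channel_id=ch,
                deadtime=self.deadtime_params[ch],
                cr_ref=gain,
                ref_power_mw=REFERENCE_POWER_MW,
            )
            for ch, gain in self.gains.items()
        }


def power_profile(cfg: ScenarioConfig, t: float, scram_at: float | None = None) -> float:
    """Reactor power (MW) at time ``t`` seconds.

    Linear ramp from zero over ``ramp_s``, constant plateau, exponential
    decay with time constant ``scram_tau_s`` after ``scram_at`` (defaults
    to the end of ``hold_s``).  Continuous everywhere.
    """
    if t < 0:
        raise ConfigurationError("time must be non-negative")
    if scram_at is None:
        scram_at = cfg.ramp_s + cfg.hold_s
    if t < cfg.ramp_s:
        return cfg.operating_power * t / cfg.ramp_s if cfg.ramp_s > 0 else cfg.operating_power
    if t < scram_at:
        return cfg.operating_power
    return cfg.operating_power * math.exp(-(t - scram_at) / cfg.scram_tau_s)


def sample_tick(
    cfg: ScenarioConfig,
    t: float,
    rng: np.random.Generator,
    power: float | None = None,
) -> BeamSample:
    """Draw one telemetry tick at time ``t``.

    True rate per channel is ``gain * power / 1.2`` (zero below the beam
    onset power); counts over the 1-s tick are Poisson about that rate
    when noise is on; the reported rate is the dead-time-distorted one.
    """
    if power is None:
        power = power_profile(cfg, t)
    cr_meas: dict[str, float] = {}
    for ch, gain in cfg.gains.items():
        true_rate = gain * power / REFERENCE_POWER_MW if power >= cfg.beam_onset_power else 0.0
        counts = float(rng.poisson(true_rate)) if cfg.noise else true_rate
        cr_meas[ch] = deadtime.distort(counts, cfg.deadtime_params[ch])
    gamma = cfg.gamma_coeff * power + cfg.gamma_background
    return BeamSample(t=t, cr_meas=cr_meas, power=power, gamma_dose_rate=gamma)


@dataclass
class SimulationResult:
    telemetry: pd.DataFrame
    dose_log: pd.DataFrame
    state: DoseState
    engine: DoseEngine
    scram_at: float | None


def run_scenario(
    cfg: ScenarioConfig,
    fld: TreatmentField,
    bc_timeline: BcTimeline | None = None,
    calibrations: Mapping[str, ChannelCalibration] | None = None,
    control_channel: str = "A",
    rundown_pct: float = 100.0,
    registration_threshold: float = 100.0,
    duration_s: float | None = None,
) -> SimulationResult:
    """Run a full irradiation scenario through the dose engine.

    In the default target-driven mode the plateau lasts until the
    engine's shutdown signal fires, after which the exponential scram
    tail is appended (and keeps accumulating dose) until power falls
    below the beam-onset threshold.  With ``duration_s`` set the run has
    a fixed length and no scram is inserted — the constant-conditions
    replay mode.  Raises :class:`ConfigurationError` if the target is
    not reached within ``max_duration_s``.
    """
    if calibrations is None:
        calibrations = cfg.calibrations()
    engine = DoseEngine(
        fld,
        calibrations,
        bc_timeline=bc_timeline,
        control_channel=control_channel,
        rundown_pct=rundown_pct,
        registration_threshold=registration_threshold,
    )
    rng = np.random.default_rng(cfg.seed)
    scram_at: float | None = None
    t = 0.0
    while True:
        if duration_s is not None:
            if t >= duration_s:
                break
            power = power_profile(cfg, t, scram_at=math.inf)
        else:
            # plateau holds until the engine calls for shutdown
            power = power_profile(cfg, t, scram_at=scram_at if scram_at is not None else math.inf)
            if scram_at is not None and power < cfg.beam_onset_power:
                break
        sample = sample_tick(cfg, t, rng, power=power)
        engine.step(sample)
        if duration_s is None and scram_at is None and engine.shutdown_signal:
            scram_at = t + 1.0
        if t > cfg.max_duration_s:
            raise ConfigurationError(
                f"target dose not reached within max_duration_s={cfg.max_duration_s:g} s"
            )
        t += 1.0
    return SimulationResult(
        telemetry=engine.telemetry_frame(),
        dose_log=engine.dose_log_frame(),
        state=engine.state,
        engine=engine,
        scram_at=scram_at,
    )
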