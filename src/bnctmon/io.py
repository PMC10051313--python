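"""Readers and writers for the monitor's on-disk formats.

All formats are plain text so sessions stay diffable and portable:

* plan files (YAML): one record per treatment field with its planning
  dose rates, planned boron concentration and target dose;
* calibration files (YAML): per-channel dead-time coefficients and
  reference counting rate at the reference power;
* scenario files (YAML): reactor/beam simulation parameters;
* foil files (YAML): activation-foil irradiation records;
* telemetry / dose-log / concentration tables (CSV), one row per second
  or per draw.

Floats round-trip exactly: CSV and JSON writing uses Python's shortest
repr, which the readers parse back to the identical double.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .beam_sim import ScenarioConfig
from .calibration import FoilIrradiation
from .deadtime import DeadTimeParams
from .dose_engine import (
    CHANNEL_COLUMNS,
    DOSE_LOG_COLUMNS,
    TELEMETRY_COLUMNS,
    BeamSample,
    ChannelCalibration,
    TreatmentField,
)
from .errors import ConfigurationError, StreamError

__all__ = [
    "load_plan",
    "save_plan",
    "load_calibrations",
    "save_calibrations",
    "load_scenario",
    "load_foils",
    "read_telemetry",
    "write_telemetry",
    "iter_samples",
    "write_dose_log",
    "read_dose_log",
]

BC_COLUMNS = ["draw_time", "r1", "r2", "r3", "mean_ppm"]


# -- plan files ----------------------------------------------------------


def load_plan(path: str | Path) -> list[TreatmentField]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "fields" not in doc or not doc["fields"]:
        raise ConfigurationError(f"plan file {path} contains no fields")
    out = []
    for rec in doc["fields"]:
        out.append(
            TreatmentField(
                field_id=str(rec["field_id"]),
                boron_dose_rate=float(rec["boron_dose_rate_cgyw_s"]),
                background_dose_rate=float(rec["background_dose_rate_cgyw_s"]),
                bc_plan=float(rec["bc_plan_ppm"]),
                target_dose=float(rec["target_dose_cgyw"]),
                status=str(rec.get("status", "open")),
            )
        )
    return out


def save_plan(fields: list[TreatmentField], path: str | Path) -> None:
    doc = {
        "fields": [
            {
                "field_id": f.field_id,
                "boron_dose_rate_cgyw_s": f.boron_dose_rate,
                "background_dose_rate_cgyw_s": f.background_dose_rate,
                "bc_plan_ppm": f.bc_plan,
                "target_dose_cgyw": f.target_dose,
                "status": f.status,
            }
            for f in fields
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# -- calibration files ---------------------------------------------------


def load_calibrations(path: str | Path) -> dict[str, ChannelCalibration]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "channels" not in doc or not doc["channels"]:
        raise ConfigurationError(f"calibration file {path} contains no channels")
    out = {}
    for rec in doc["channels"]:
        ch = str(rec["channel_id"])
        out[ch] = ChannelCalibration(
            channel_id=ch,
            deadtime=DeadTimeParams(a_lin=float(rec["A"]), b_quad=float(rec["B"])),
            cr_ref=float(rec["cr_ref"]),
            ref_power_mw=float(rec.get("ref_power_MW", 1.2)),
        )
    return out


def save_calibrations(cals: dict[str, ChannelCalibration], path: str | Path) -> None:
    doc = {
        "channels": [
            {
                "channel_id": c.channel_id,
                "A": c.deadtime.a_lin,
                "B": c.deadtime.b_quad,
                "cr_ref": c.cr_ref,
                "ref_power_MW": c.ref_power_mw,
            }
            for c in cals.values()
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# -- scenario files ------------------------------------------------------


def load_scenario(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    deadtime_params = {
        str(ch): DeadTimeParams(a_lin=float(rec["A"]), b_quad=float(rec["B"]))
        for ch, rec in (doc.pop("deadtime_params", None) or {}).items()
    }
    gains = {str(ch): float(g) for ch, g in (doc.pop("gains", None) or {}).items()}
    kwargs = dict(doc)
    if gains:
        kwargs["gains"] = gains
    if deadtime_params:
        kwargs["deadtime_params"] = deadtime_params
    try:
        return ScenarioConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"bad scenario file {path}: {exc}") from exc


# -- foil files ----------------------------------------------------------


def load_foils(path: str | Path, cr_series: list[float]) -> list[FoilIrradiation]:
    """Load foil records, attaching the channel counting-rate series."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    recs = doc.get("foils") if isinstance(doc, dict) else None
    if recs is None:
        recs = [doc] if isinstance(doc, dict) else doc
    if not recs:
        raise ConfigurationError(f"foil file {path} contains no records")
    out = []
    for rec in recs:
        duration = int(rec["duration_s"])
        out.append(
            FoilIrradiation(
                rr_ref=float(rec["rr_ref"]),
                activity=float(rec["activity"]),
                decay_const=float(rec["decay_const"]),
                duration=duration,
                cr_series=tuple(cr_series[:duration]),
                foil=str(rec.get("foil", "Au")),
            )
        )
    return out


# -- telemetry / dose-log CSV -------------------------------------------


def write_telemetry(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, columns=TELEMETRY_COLUMNS)


def read_telemetry(path: str | Path) -> pd.DataFrame:
    """Read a telemetry CSV, validating structure row by row.

    Raises :class:`StreamError` naming the 1-based file line of the first
    malformed row (missing value, negative rate, non-increasing time).
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TELEMETRY_COLUMNS if c not in frame.columns]
    if missing:
        raise StreamError(f"{path}: missing telemetry columns {missing}")
    frame = frame[TELEMETRY_COLUMNS]
    bad = frame.isna().any(axis=1)
    rate_cols = ["cr_a", "cr_b", "cr_c"]
    bad |= (frame[rate_cols] < 0).any(axis=1) | (frame["power_mw"] < 0)
    if bad.any():
        idx = int(bad.idxmax())
        raise StreamError(f"{path}: malformed telemetry row at line {idx + 2}")
    t = frame["t_s"].to_numpy()
    if len(t) > 1:
        nonmono = np.nonzero(np.diff(t) <= 0)[0]
        if nonmono.size:
            raise StreamError(
                f"{path}: non-increasing timestamp at line {int(nonmono[0]) + 3}"
            )
    return frame


def iter_samples(frame: pd.DataFrame, channels: list[str] | None = None) -> Iterator[BeamSample]:
    """Yield :class:`BeamSample` ticks from a telemetry frame."""
    if channels is None:
        channels = list(CHANNEL_COLUMNS)
    cols = {ch: CHANNEL_COLUMNS[ch] for ch in channels}
    for row in frame.itertuples(index=False):
        yield BeamSample(
            t=float(row.t_s),
            cr_meas={ch: float(getattr(row, col)) for ch, col in cols.items()},
            power=float(row.power_mw),
            gamma_dose_rate=float(row.gamma),
        )


def write_dose_log(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, columns=DOSE_LOG_COLUMNS)


def read_dose_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
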