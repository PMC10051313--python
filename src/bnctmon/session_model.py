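"""Persistent model of treatment and experiment sessions.

A session ties together one subject (patient, animal, or cell sample),
the candidate treatment fields imported from the planning system, the
boron-concentration timeline built from triplicate ICP-OES readings, and
the telemetry and dose logs of the irradiation.  Fields move through the
lifecycle open -> irradiation -> final; concentration measurements taken
mid-irradiation are pushed to the dose engine so the corrected
prescription dose tracks the latest blood values.

Plans are typically offered per field geometry at several planned boron
concentrations (e.g. a two-field plan at 30 ppm and at 40 ppm); plan
selection picks, within each geometry, the variant whose planned
concentration is nearest the measured blood value, breaking ties upward.

Persistence is a flat directory of JSON (metadata) and CSV (time
series) — diffable and exactly round-tripping every numeric field.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as bio
from .calibration import QaqcRecord
from .dose_engine import (
    BcTimeline,
    BeamSample,
    ChannelCalibration,
    DoseEngine,
    DOSE_LOG_COLUMNS,
    FieldStatus,
    TELEMETRY_COLUMNS,
    TreatmentField,
)
from .errors import DomainError, StateError

__all__ = ["Subject", "BCMeasurement", "Session", "select_variants"]

SUBJECT_KINDS = {"patient", "animal", "cell"}
EXPORT_TABLES = ("telemetry", "dose", "bc", "summary")


@dataclass(frozen=True)
class Subject:
    """An anonymized irradiation subject."""

    subject_id: str
    kind: str
    label: str = ""
    indication: str = ""

    def __post_init__(self) -> None:
        if self.kind not in SUBJECT_KINDS:
            raise DomainError(f"subject kind must be one of {sorted(SUBJECT_KINDS)}")


@dataclass(frozen=True)
class BCMeasurement:
    """One timed sample draw with its triplicate readings, ppm."""

    draw_time: float
    readings: tuple[float, float, float]
    mean_ppm: float = dc_field(init=False)

    def __post_init__(self) -> None:
        readings = tuple(float(r) for r in self.readings)
        if len(readings) != 3:
            raise DomainError(f"expected exactly 3 readings, got {len(readings)}")
        if any(r <= 0 for r in readings):
            raise DomainError("concentration readings must be positive")
        object.__setattr__(self, "readings", readings)
        object.__setattr__(self, "mean_ppm", statistics.fmean(readings))


def select_variants(
    candidates: Sequence[TreatmentField],
    measured_bc: float,
    geometries: Sequence[str] | None = None,
) -> list[TreatmentField]:
    """Pick, per field geometry, the planned-BC variant nearest ``measured_bc``.

    Ties between equally distant planned concentrations go to the higher
    one.  ``geometries`` restricts the choice to the named field ids
    (e.g. the two-field plan the physician selected); by default all
    geometries present among the candidates are used.
    """
    if not candidates:
        raise DomainError("empty candidate set")
    groups: dict[str, list[TreatmentField]] = {}
    for f in candidates:
        groups.setdefault(f.field_id, []).append(f)
    if geometries is None:
        geometries = list(groups)
    chosen = []
    for geom in geometries:
        if geom not in groups:
            raise DomainError(f"no candidate field with id {geom!r}")
        best = min(
            groups[geom],
            key=lambda f: (abs(f.bc_plan - measured_bc), -f.bc_plan),
        )
        chosen.append(best)
    return chosen


class Session:
    """One irradiation session: subject, fields, logs, lifecycle."""

    def __init__(self, subject: Subject, fields: Sequence[TreatmentField] = ()) -> None:
        self.subject = subject
        self.fields: list[TreatmentField] = list(fields)
        self.selected: list[TreatmentField] = []
        self.bc_measurements: list[BCMeasurement] = []
        self.bc_timeline = BcTimeline()
        self.qaqc_log: list[QaqcRecord] = []
        self.timestamps: dict[str, float] = {}
        self.engine: DoseEngine | None = None
        self._active: TreatmentField | None = None
        # frozen per-field logs, keyed (field_id, bc_plan)
        self.telemetry_logs: dict[tuple[str, float], pd.DataFrame] = {}
        self.dose_logs: dict[tuple[str, float], pd.DataFrame] = {}

    # -- boron concentration --------------------------------------------

    def record_bc(self, draw_time: float, readings: Sequence[float]) -> BCMeasurement:
        """Store a triplicate draw; its mean feeds the dose engine."""
        if len(readings) != 3:
            raise DomainError(f"expected exactly 3 readings, got {len(readings)}")
        m = BCMeasurement(draw_time=float(draw_time), readings=tuple(readings))
        self.bc_measurements.append(m)
        if self.engine is not None:
            self.engine.apply_bc_update(m.mean_ppm, at=m.draw_time)
        else:
            self.bc_timeline.add(m.draw_time, m.mean_ppm)
        return m

    # -- plan lifecycle --------------------------------------------------

    def select_plan(
        self,
        measured_bc: float,
        geometries: Sequence[str] | None = None,
    ) -> list[TreatmentField]:
        """Choose the planned-BC variant of each geometry for irradiation."""
        self.selected = select_variants(self.fields, measured_bc, geometries)
        return self.selected

    def _find(self, field_id: str) -> TreatmentField:
        pool = self.selected or self.fields
        for f in pool:
            if f.field_id == field_id:
                return f
        raise StateError(f"no field {field_id!r} in session")

    def start_field(
        self,
        field_id: str,
        calibrations: Mapping[str, ChannelCalibration],
        control_channel: str = "A",
        rundown_pct: float = 100.0,
        registration_threshold: float = 100.0,
    ) -> DoseEngine:
        """Move one field into irradiation and attach a dose engine.

        Only one field may be under irradiation at a time.
        """
        if self._active is not None:
            raise StateError(
                f"field {self._active.field_id!r} is already under irradiation"
            )
        fld = self._find(field_id)
        fld.advance_status(FieldStatus.IRRADIATION)
        self._active = fld
        self.engine = DoseEngine(
            fld,
            calibrations,
            bc_timeline=self.bc_timeline,
            control_channel=control_channel,
            rundown_pct=rundown_pct,
            registration_threshold=registration_threshold,
        )
        return self.engine

    def step(self, sample: BeamSample):
        if self.engine is None:
            raise StateError("no field under irradiation")
        return self.engine.step(sample)

    def finalize_field(self, field_id: str) -> TreatmentField:
        """Close out an irradiated field; its logs are frozen.

        Re-finalizing an already final field is a no-op; finalizing an
        open (never irradiated) field is an error, as is finalizing
        before any dose tick registered.
        """
        fld = self._find(field_id)
        if fld.status == FieldStatus.FINAL:
            return fld
        if fld.status != FieldStatus.IRRADIATION:
            raise StateError(f"cannot finalize field in status {fld.status!r}")
        if self.engine is None or self.engine.state.elapsed_s <= 0:
            raise StateError("cannot finalize a field with no registered dose")
        fld.advance_status(FieldStatus.FINAL)
        key = (fld.field_id, fld.bc_plan)
        self.telemetry_logs[key] = self.engine.telemetry_frame()
        self.dose_logs[key] = self.engine.dose_log_frame()
        self.engine = None
        self._active = None
        return fld

    # -- query / export --------------------------------------------------

    def _table(self, what: str) -> pd.DataFrame:
        if what == "telemetry":
            frames = list(self.telemetry_logs.values())
            if self.engine is not None:
                frames.append(self.engine.telemetry_frame())
            return (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame(columns=TELEMETRY_COLUMNS)
            )
        if what == "dose":
            frames = list(self.dose_logs.values())
            if self.engine is not None:
                frames.append(self.engine.dose_log_frame())
            return (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame(columns=DOSE_LOG_COLUMNS)
            )
        if what == "bc":
            return pd.DataFrame(
                [
                    {
                        "draw_time": m.draw_time,
                        "r1": m.readings[0],
                        "r2": m.readings[1],
                        "r3": m.readings[2],
                        "mean_ppm": m.mean_ppm,
                    }
                    for m in self.bc_measurements
                ],
                columns=bio.BC_COLUMNS,
            )
        if what == "summary":
            rows = []
            for f in self.fields:
                key = (f.field_id, f.bc_plan)
                dose = self.dose_logs.get(key)
                rows.append(
                    {
                        "field_id": f.field_id,
                        "bc_plan_ppm": f.bc_plan,
                        "status": f.status,
                        "target_dose_cgyw": f.target_dose,
                        "accumulated_cgyw": (
                            float(dose["accumulated"].iloc[-1]) if dose is not None and len(dose) else 0.0
                        ),
                        "corrected_cgyw": (
                            float(dose["corrected"].iloc[-1]) if dose is not None and len(dose) else 0.0
                        ),
                        "elapsed_s": (
                            float((dose["dose_increment"] > 0).sum()) if dose is not None else 0.0
                        ),
                    }
                )
            return pd.DataFrame(
                rows,
                columns=[
                    "field_id",
                    "bc_plan_ppm",
                    "status",
                    "target_dose_cgyw",
                    "accumulated_cgyw",
                    "corrected_cgyw",
                    "elapsed_s",
                ],
            )
        raise DomainError(f"unknown table {what!r}; expected one of {EXPORT_TABLES}")

    def export_csv(self, what: str, path: str | Path | None = None) -> str:
        """Render one session table as CSV text (optionally writing it)."""
        text = self._table(what).to_csv(index=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    # -- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "subject": {
                "subject_id": self.subject.subject_id,
                "kind": self.subject.kind,
                "label": self.subject.label,
                "indication": self.subject.indication,
            },
            "selected": [[f.field_id, f.bc_plan] for f in self.selected],
            "timestamps": self.timestamps,
            "qaqc": [
                {
                    "timestamp": r.timestamp,
                    "ic_current": r.ic_current,
                    "band_low": r.reference_band[0],
                    "band_high": r.reference_band[1],
                    "pass": r.pass_flag,
                }
                for r in self.qaqc_log
            ],
        }
        (d / "session.json").write_text(json.dumps(meta, indent=1))
        bio.save_plan(self.fields, d / "plan.yaml")
        (d / "bc.csv").write_text(self.export_csv("bc"))
        (d / "telemetry.csv").write_text(self.export_csv("telemetry"))
        (d / "dose.csv").write_text(self.export_csv("dose"))

    @classmethod
    def load(cls, directory: str | Path) -> "Session":
        d = Path(directory)
        meta = json.loads((d / "session.json").read_text())
        subject = Subject(**meta["subject"])
        fields = bio.load_plan(d / "plan.yaml")
        session = cls(subject, fields)
        selected_keys = {tuple(k) for k in meta.get("selected", [])}
        session.selected = [
            f for f in fields if (f.field_id, f.bc_plan) in selected_keys
        ]
        session.timestamps = dict(meta.get("timestamps", {}))
        for rec in meta.get("qaqc", []):
            session.qaqc_log.append(
                QaqcRecord(
                    timestamp=rec["timestamp"],
                    ic_current=rec["ic_current"],
                    reference_band=(rec["band_low"], rec["band_high"]),
                )
            )
        bc = pd.read_csv(d / "bc.csv", float_precision="round_trip")
        for row in bc.itertuples(index=False):
            m = BCMeasurement(
                draw_time=float(row.draw_time),
                readings=(float(row.r1), float(row.r2), float(row.r3)),
            )
            session.bc_measurements.append(m)
            session.bc_timeline.add(m.draw_time, m.mean_ppm)
        tele = pd.read_csv(d / "telemetry.csv", float_precision="round_trip")
        dose = pd.read_csv(d / "dose.csv", float_precision="round_trip")
        finals = [f for f in fields if f.status == FieldStatus.FINAL]
        if len(finals) == 1 and len(dose):
            key = (finals[0].field_id, finals[0].bc_plan)
            session.telemetry_logs[key] = tele
            session.dose_logs[key] = dose
        elif len(tele) or len(dose):
            session.telemetry_logs[("", 0.0)] = tele
            session.dose_logs[("", 0.0)] = dose
        return session
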