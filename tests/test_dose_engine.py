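"""Boron-weighted dose accumulation: increments, registration, updates."""

import math

import numpy as np
import pytest

from bnctmon import deadtime
from bnctmon.dose_engine import (
    BcTimeline,
    BeamSample,
    ChannelCalibration,
    DoseEngine,
    TreatmentField,
    dose_increment,
    remaining_time,
)
from bnctmon.errors import ConfigurationError, DomainError, StateError, StreamError

from conftest import CR_REF, IDENTITY, LOSSY, constant_samples


def test_increment_matches_printed_rates(animal_field, control_cal):
    """0.1417 + 0.18 cGy-w/s at unit ratios gives 0.3217 cGy-w per second."""
    sample = BeamSample(t=0.0, cr_meas={"A": deadtime.distort(CR_REF, LOSSY)})
    inc = dose_increment(sample, animal_field, bc_now=animal_field.bc_plan, cal=control_cal)
    assert inc == pytest.approx(0.3217, rel=1e-9)


def test_increment_zero_beam(animal_field, control_cal):
    sample = BeamSample(t=0.0, cr_meas={"A": 0.0})
    assert dose_increment(sample, animal_field, animal_field.bc_plan, control_cal) == 0.0


def test_increment_unit_bc_ratio_is_sum_of_rates(animal_field, control_cal):
    """At BCmeas == BCplan the boron weighting drops out."""
    sample = BeamSample(t=0.0, cr_meas={"A": deadtime.distort(0.5 * CR_REF, LOSSY)})
    inc = dose_increment(sample, animal_field, animal_field.bc_plan, control_cal)
    assert inc == pytest.approx((0.1417 + 0.18) * 0.5, rel=1e-9)


def test_increment_configuration_errors(animal_field, lossy_params):
    bad_cal = ChannelCalibration("A", lossy_params, cr_ref=0.0)
    sample = BeamSample(t=0.0, cr_meas={"A": 1.0})
    with pytest.raises(ConfigurationError):
        dose_increment(sample, animal_field, 10.0, bad_cal)
    with pytest.raises(ConfigurationError):
        TreatmentField("X", 0.1, 0.1, bc_plan=0.0, target_dose=1.0)


def test_registration_threshold_and_latch(engine):
    """No dose below 100 counts/tick; once above, the latch holds."""
    st = engine.step(BeamSample(t=0.0, cr_meas={"A": 50.0}))
    assert not st.registering and st.accumulated_dose == 0.0 and st.elapsed_s == 0.0
    st = engine.step(BeamSample(t=1.0, cr_meas={"A": 100.0}))  # threshold is strict
    assert not st.registering
    st = engine.step(BeamSample(t=2.0, cr_meas={"A": 101.0}))
    assert st.registering and st.accumulated_dose > 0.0
    st = engine.step(BeamSample(t=3.0, cr_meas={"A": 10.0}))  # dip below: still on
    assert st.registering and st.elapsed_s == 2.0


def test_constant_stream_closed_form(engine, animal_field):
    """n ticks at ratio r give exactly n * r * (Db10 + Dother)."""
    n, true_rate = 500, CR_REF * 1.28 / 1.2
    for s in constant_samples(n, true_rate):
        engine.step(s)
    expected = n * (1.28 / 1.2) * (0.1417 + 0.18)
    assert engine.state.accumulated_dose == pytest.approx(expected, rel=1e-9)
    assert engine.state.elapsed_s == n


def test_additivity_under_stream_partition(animal_field, control_cal):
    """Total dose equals the sum of per-partition dose increments."""
    rng = np.random.default_rng(42)
    rates = rng.uniform(0.0, 1.4e5, size=400)
    samples = [
        BeamSample(t=float(i), cr_meas={"A": deadtime.distort(r, LOSSY)})
        for i, r in enumerate(rates)
    ]
    single = DoseEngine(animal_field, {"A": control_cal}, registration_threshold=0.0)
    for s in samples:
        single.step(s)
    # two-pass: independent oracle summing logged increments over arbitrary cuts
    log = single.dose_log_frame()
    for cut in (1, 57, 200, 399):
        assert log["dose_increment"][:cut].sum() + log["dose_increment"][cut:].sum() == pytest.approx(
            single.state.accumulated_dose, rel=1e-12
        )
    # and feeding the same stream in chunks produces the identical state
    chunked = DoseEngine(
        TreatmentField("CH1", 0.1417, 0.18, 12.95, 600.0),
        {"A": control_cal},
        registration_threshold=0.0,
    )
    for chunk in (samples[:57], samples[57:200], samples[200:]):
        for s in chunk:
            chunked.step(s)
    assert chunked.state.accumulated_dose == pytest.approx(
        single.state.accumulated_dose, rel=0
    )


def test_out_of_order_timestamps(engine):
    engine.step(BeamSample(t=5.0, cr_meas={"A": 1000.0}))
    with pytest.raises(StreamError):
        engine.step(BeamSample(t=5.0, cr_meas={"A": 1000.0}))
    with pytest.raises(StreamError):
        engine.step(BeamSample(t=4.0, cr_meas={"A": 1000.0}))


class TestPauseResume:
    def test_paused_samples_logged_not_accumulated(self, engine):
        for s in constant_samples(10, CR_REF):
            engine.step(s)
        dose_before = engine.state.accumulated_dose
        engine.pause()
        for s in constant_samples(100, CR_REF, start=10.0):
            engine.step(s)
        assert engine.state.accumulated_dose == dose_before
        assert engine.state.elapsed_s == 10.0
        assert len(engine.telemetry_frame()) == 110  # paused ticks still logged
        engine.resume()
        engine.step(constant_samples(1, CR_REF, start=110.0)[0])
        assert engine.state.accumulated_dose > dose_before

    def test_pause_resume_no_samples_is_identity(self, engine):
        for s in constant_samples(5, CR_REF):
            engine.step(s)
        before = engine.state
        engine.pause()
        engine.resume()
        assert engine.state == before

    def test_state_errors(self, engine):
        with pytest.raises(StateError):
            engine.resume()
        engine.pause()
        with pytest.raises(StateError):
            engine.pause()


class TestBcUpdates:
    def brute_force_corrected(self, log_ratios, times, timeline, fld):
        total = 0.0
        for t, r in zip(times, log_ratios):
            bc = timeline.value_at(t, default=fld.bc_plan)
            total += (fld.boron_dose_rate * bc / fld.bc_plan + fld.background_dose_rate) * r
        return total

    def test_update_equal_to_plan_is_neutral(self, engine, animal_field):
        for s in constant_samples(50, CR_REF):
            engine.step(s)
        st = engine.apply_bc_update(animal_field.bc_plan, at=0.0)
        assert st.corrected_dose == pytest.approx(st.accumulated_dose, rel=1e-12)

    def test_halving_bc_halves_boron_component(self, engine, animal_field):
        n = 80
        for s in constant_samples(n, CR_REF):
            engine.step(s)
        st0 = engine.state
        st = engine.apply_bc_update(animal_field.bc_plan / 2.0, at=0.0)
        boron, background = 0.1417 * n, 0.18 * n
        assert st0.accumulated_dose == pytest.approx(boron + background, rel=1e-9)
        assert st.corrected_dose == pytest.approx(boron / 2.0 + background, rel=1e-9)
        assert st.accumulated_dose == pytest.approx(st0.accumulated_dose, rel=0)
        # cross-check against the literal per-tick oracle
        oracle = self.brute_force_corrected(
            [1.0] * n, list(range(n)), engine.bc_timeline, animal_field
        )
        assert st.corrected_dose == pytest.approx(oracle, rel=1e-12)

    def test_update_on_empty_session(self, engine):
        st = engine.apply_bc_update(20.0, at=0.0)
        assert st.accumulated_dose == 0.0 and st.corrected_dose == 0.0
        assert len(engine.bc_timeline) == 1

    def test_update_before_session_start(self, engine):
        engine.step(BeamSample(t=100.0, cr_meas={"A": 1000.0}))
        with pytest.raises(DomainError):
            engine.apply_bc_update(20.0, at=50.0)

    def test_idempotence(self, engine, animal_field):
        for s in constant_samples(60, CR_REF):
            engine.step(s)
        first = engine.apply_bc_update(25.9, at=30.0).corrected_dose
        second = engine.apply_bc_update(25.9, at=30.0).corrected_dose
        assert second == first


@pytest.mark.parametrize(
    "remaining, rate, expected",
    [(300.0, 0.3217, 932.5458), (0.0, 0.5, 0.0), (10.0, 0.0, None)],
)
def test_remaining_time(remaining, rate, expected):
    got = remaining_time(remaining, rate)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected, rel=1e-4)


class TestShutdownSignal:
    def test_fires_at_target_and_latches(self, animal_field, control_cal):
        eng = DoseEngine(animal_field, {"A": control_cal})
        flips = 0
        prev = False
        for s in constant_samples(1900, CR_REF * 1.28 / 1.2):
            eng.step(s)
            if eng.shutdown_signal != prev:
                flips += 1
                prev = eng.shutdown_signal
        assert eng.shutdown_signal and flips == 1
        assert eng.state.accumulated_dose >= animal_field.target_dose

    def test_inclusive_rundown_boundary(self, control_cal):
        fld = TreatmentField("F", 0.0, 1.0, bc_plan=10.0, target_dose=100.0)
        eng = DoseEngine(fld, {"A": control_cal}, rundown_pct=95.0)
        for s in constant_samples(95, CR_REF):
            eng.step(s)
        assert eng.state.corrected_dose == pytest.approx(95.0, rel=1e-12)
        assert eng.shutdown_signal

    def test_zero_dose_no_signal(self, engine):
        assert not engine.shutdown_signal


def test_cross_check_warning(animal_field, lossy_params):
    cals = {
        "A": ChannelCalibration("A", lossy_params, cr_ref=CR_REF),
        "B": ChannelCalibration("B", lossy_params, cr_ref=CR_REF),
    }
    eng = DoseEngine(animal_field, cals, cross_check_tol=0.05)
    ok = deadtime.distort(CR_REF, lossy_params)
    low = deadtime.distort(0.9 * CR_REF, lossy_params)
    eng.step(BeamSample(t=0.0, cr_meas={"A": ok, "B": ok}))
    assert not eng.warnings
    eng.step(BeamSample(t=1.0, cr_meas={"A": ok, "B": low}))
    assert len(eng.warnings) == 1 and "channel B" in eng.warnings[0]


def test_bc_timeline_semantics():
    tl = BcTimeline([(10.0, 20.0), (50.0, 30.0)])
    assert tl.value_at(5.0, default=12.0) == 12.0  # before first entry
    assert tl.value_at(10.0, default=12.0) == 20.0
    assert tl.value_at(49.9, default=12.0) == 20.0  # carried forward
    assert tl.value_at(500.0, default=12.0) == 30.0
    with pytest.raises(DomainError):
        tl.add(40.0, 25.0)  # reordering
    with pytest.raises(DomainError):
        tl.add(60.0, -1.0)
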