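import pytest

from bnctmon import (
    BeamSample,
    ChannelCalibration,
    DeadTimeParams,
    DoseEngine,
    TreatmentField,
)
from bnctmon.deadtime import distort

#: Mildly lossy channel: ~0.5% counting loss at 5e4 counts/s.
LOSSY = DeadTimeParams(a_lin=1.0, b_quad=-1e-7)
IDENTITY = DeadTimeParams(a_lin=1.0, b_quad=0.0)

CR_REF = 1.0e5  # control-channel reference rate at 1.2 MW, counts/s


@pytest.fixture
def lossy_params():
    return LOSSY


@pytest.fixture
def animal_field():
    """The mouse-experiment prescription: 600 cGy-w target, 12.95 ppm."""
    return TreatmentField(
        field_id="CH1",
        boron_dose_rate=0.1417,
        background_dose_rate=0.18,
        bc_plan=12.95,
        target_dose=600.0,
    )


@pytest.fixture
def control_cal():
    return ChannelCalibration(channel_id="A", deadtime=LOSSY, cr_ref=CR_REF)


@pytest.fixture
def engine(animal_field, control_cal):
    return DoseEngine(animal_field, {"A": control_cal})


def constant_samples(n, true_rate, params=LOSSY, start=0.0, channel="A", power=1.28):
    """n one-second ticks at a constant true counting rate."""
    meas = distort(true_rate, params)
    return [
        BeamSample(t=start + i, cr_meas={channel: meas}, power=power)
        for i in range(n)
    ]
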