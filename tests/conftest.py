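import numpy as np
import pytest

from caflux import (
    CellParams,
    GroupEffect,
    RoiLayout,
    RoiSpec,
    make_default_schedules,
)


@pytest.fixture(scope="session")
def evoked_schedule():
    return make_default_schedules()[0]


@pytest.fixture(scope="session")
def plate_schedule():
    return make_default_schedules()[1]


@pytest.fixture
def quiet_params():
    """Noise-free, drift-free cell: the trace is the analytic model."""
    return CellParams(noise_sd=0.0, drift_per_s=0.0)


@pytest.fixture
def control_effect():
    return GroupEffect(label="control")


@pytest.fixture
def three_roi_layout():
    return RoiLayout(
        frame_shape=(32, 48),
        rois=(
            RoiSpec(label=1, y0=2, x0=2, height=8, width=8),
            RoiSpec(label=2, y0=2, x0=14, height=4, width=8),
            RoiSpec(label=3, y0=14, x0=2, height=4, width=4),
        ),
    )
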