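import numpy as np
import pytest

from clsense.calibration import CalibrationFit
from clsense.trace_model import (
    Buffer,
    Condition,
    NeuronType,
    Phase,
    ROITrace,
    SliceRecording,
)


@pytest.fixture
def sensor() -> CalibrationFit:
    """Default sensor constants used throughout the synthetic generators."""
    return CalibrationFit(kd_mM=108.8, r_min=0.98, r_max=2.92, hill_p=2.91)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def avp_day() -> Condition:
    return Condition(NeuronType.AVP, Phase.DAY, Buffer.BICARBONATE)


def make_trace(
    slice_id="s1",
    roi_id="r1",
    n=100,
    dt=5.0,
    f436=600.0,
    f500=500.0,
    exposure=100.0,
    is_background=False,
) -> ROITrace:
    t = np.arange(n) * dt
    f436 = np.full(n, f436) if np.isscalar(f436) else np.asarray(f436, float)
    f500 = np.full(n, f500) if np.isscalar(f500) else np.asarray(f500, float)
    return ROITrace(
        slice_id=slice_id,
        roi_id=roi_id,
        time_s=t,
        f436=f436,
        f500=f500,
        exposure500_ms=exposure,
        is_background=is_background,
    )


def make_recording(slice_id="s1", n_rois=2, condition=None, events=(),
                   n=100, dt=5.0) -> SliceRecording:
    traces = [
        make_trace(slice_id=slice_id, roi_id=f"r{i}", n=n, dt=dt)
        for i in range(n_rois)
    ]
    traces.append(
        make_trace(slice_id=slice_id, roi_id="bg", n=n, dt=dt,
                   f436=50.0, f500=80.0, is_background=True)
    )
    return SliceRecording(
        slice_id=slice_id,
        condition=condition,
        traces=traces,
        events=list(events),
    )
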