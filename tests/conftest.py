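import numpy as np
import pytest

from qcucvp import (
    CaptureProtocol,
    CVPWaveformSpec,
    VesselParams,
    load_study_table,
    synth_capture,
)


@pytest.fixture(scope="session")
def study_table():
    return load_study_table()


@pytest.fixture(scope="session")
def quiet_protocol():
    """Force protocol without sensor noise, for deterministic captures."""
    return CaptureProtocol(force_noise_sd=0.0)


@pytest.fixture(scope="session")
def default_capture():
    """One representative capture at 5 mmHg mean CVP with all physiological
    variation enabled."""
    return synth_capture(5.0, VesselParams(), seed=3)


@pytest.fixture(scope="session")
def still_capture(quiet_protocol):
    """Capture with every source of variation disabled: constant CVP, no
    cardiac morphology, no respiration, no noise, no carotid coupling."""
    spec = CVPWaveformSpec(
        mean_cvp=5.0, resp_amplitude=0.0, noise_sd=0.0, component_amplitudes={}
    )
    return synth_capture(
        5.0, VesselParams(kappa=0.0), protocol=quiet_protocol, cvp_spec=spec, seed=1
    )


def hold_window(capture):
    """The three frame-aligned hold-phase channels of a capture."""
    from qcucvp import TimeSeries

    sl = capture.phase_slice("hold")
    dt = capture.ijv_area.dt

    def win(ts):
        return TimeSeries(ts.t0 + sl.start * dt, dt, ts.values[sl], ts.units)

    return win(capture.ijv_area), win(capture.force), win(capture.carotid_pressure)


@pytest.fixture(scope="session")
def ramp_force_increment(quiet_protocol):
    return quiet_protocol.ramp_rate * 0.01  # N per sample at 100 Hz
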