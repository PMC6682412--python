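import numpy as np
import pytest

from redoxtrace.redox import CalibrationSet
from redoxtrace.simulate import (
    DEFAULT_CALIBRATION,
    FlowSimConfig,
    ImagingSimConfig,
    simulate_flow_experiment,
    simulate_timelapse,
)


@pytest.fixture(scope="session")
def calib() -> CalibrationSet:
    """Hand-checkable calibration used throughout the unit tests."""
    return CalibrationSet(R_red=1.0, R_ox=5.0, i488_red=1.0, i488_ox=0.5)


@pytest.fixture(scope="session")
def default_calib() -> CalibrationSet:
    return DEFAULT_CALIBRATION


@pytest.fixture(scope="session")
def small_flow():
    """A compact flow-cytometry simulation shared across tests."""
    cfg = FlowSimConfig(
        seed=11,
        n_events_per_sample=800,
        timepoints=(0.0, 15.0, 120.0, 1440.0),
        n_replicates=2,
    )
    events, truth = simulate_flow_experiment(cfg)
    return cfg, events, truth


@pytest.fixture(scope="session")
def small_stack():
    """A compact time-lapse simulation (10 cells, 8 frames) shared across tests."""
    cfg = ImagingSimConfig(seed=7, n_cells=10, n_frames=8, field_size=(192, 192))
    stack, truth = simulate_timelapse(cfg)
    return cfg, stack, truth
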