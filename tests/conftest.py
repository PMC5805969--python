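import numpy as np
import pytest

from thermorad import (
    AlphaRParams,
    CellLine,
    CycleConfig,
    DeathDynamics,
    ExperimentConfig,
    Grid,
    PhaseSensitivity,
    TreatmentSchedule,
)

HCT116_RT = AlphaRParams.lq(0.5, 0.042)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cycle():
    return CycleConfig()


@pytest.fixture
def hct116():
    return CellLine()


@pytest.fixture
def uniform_cell_line():
    """Cell line with phase-independent radiosensitivity (gamma = 1)."""
    return CellLine(gamma_override=PhaseSensitivity.identity())


def small_config(**overrides) -> ExperimentConfig:
    """Desk-scale experiment on a small circular grid (diameter 101 voxels)."""
    defaults = dict(
        well_diameter_mm=0.101,
        voxel_edge_um=1.0,
        n_initial=200,
        duration_h=100.0,
        sample_interval_h=2.0,
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


@pytest.fixture
def small_cfg():
    return small_config()
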