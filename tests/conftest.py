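import numpy as np
import pytest

from epeesim import ParticipationModel, SimulationConfig


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_config() -> SimulationConfig:
    """A fast config: 36 athletes, 3 seasons, 4 events, full participation."""
    return SimulationConfig(
        n_athletes=36,
        n_seasons=3,
        n_tournaments_per_season=4,
        n_runs=2,
        participation_model=ParticipationModel.full(4),
    )


@pytest.fixture
def deterministic_config() -> SimulationConfig:
    """Pure-talent dynamics: a = 1, doubles off, full participation."""
    return SimulationConfig(
        n_athletes=36,
        n_seasons=3,
        n_tournaments_per_season=4,
        n_runs=1,
        talent_strength=1.0,
        double_prefactor=0.0,
        participation_model=ParticipationModel.full(4),
    )
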