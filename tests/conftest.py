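import numpy as np
import pytest

from chronotopy import (
    BirthSimConfig,
    BirthWave,
    SectionSimConfig,
    make_birth_counts,
    make_section,
)


@pytest.fixture(scope="session")
def clean_section():
    """A jitter-free rotated section plus its canonical ground truth."""
    cfg = SectionSimConfig(n_cells=400, rotation_deg=30.0, jitter_sd=0.0, seed=11)
    raw, landmarks, truth = make_section(cfg)
    return cfg, raw, landmarks, truth


@pytest.fixture(scope="session")
def birth_counts():
    """A three-family EdU count table at the half-day pulse design."""
    cfg = BirthSimConfig(
        families={
            "early": BirthWave(11.0, 0.4),
            "mid": BirthWave(11.5, 0.4),
            "late": BirthWave(12.0, 0.4),
        },
        seed=7,
    )
    return cfg, make_birth_counts(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
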