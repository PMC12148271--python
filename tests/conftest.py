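import numpy as np
import pytest

from sudtraj.simulate import SimConfig, StudySpec, generate_cohort


@pytest.fixture(scope="session")
def uniform_cohort():
    """One-study lifespan cohort with flat prevalence (selection decoupled
    from age) used by several modules."""
    cfg = SimConfig(
        seed=9,
        prev_width=1e6,
        studies=(StudySpec("u", 8, 70, 2000, 0.5, 1),),
        batch_shift_sd=0.0,
        batch_scale_sd=0.0,
    )
    scans, manifest = generate_cohort(cfg)
    return cfg, scans, manifest


@pytest.fixture(scope="session")
def default_cohort():
    """The multi-study default configuration."""
    cfg = SimConfig(seed=3)
    scans, manifest = generate_cohort(cfg)
    return cfg, scans, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(0)
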