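import numpy as np
import pytest

from fmaue.preprocessing import AugmentConfig, PreprocessConfig, FUNCTIONAL
from fmaue.pipeline import PipelineConfig
from fmaue.synthetic import ImpairmentProfile, simulate_subject


@pytest.fixture(scope="session")
def moderate_profile() -> ImpairmentProfile:
    return ImpairmentProfile(np.array([0.3, 0.6, 0.2, 0.8]))


@pytest.fixture(scope="session")
def synthetic_session(moderate_profile):
    """One moderately impaired synthetic subject, reused across tests."""
    return simulate_subject(moderate_profile, seed=42, subject_id="S42")


@pytest.fixture(scope="session")
def healthy_session():
    return simulate_subject(
        ImpairmentProfile(np.zeros(4)), seed=7, subject_id="S07")


@pytest.fixture(scope="session")
def fast_pipeline_cfg() -> PipelineConfig:
    """Functional filter preset, no signal augmentation (fast paths)."""
    return PipelineConfig(
        preprocess=PreprocessConfig(filter=FUNCTIONAL),
        augment=AugmentConfig(copies_per_trial=0),
    )
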