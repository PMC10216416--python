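import numpy as np
import pytest

from nodalrad.preprocessing import ImageVolume, NodeVOI


@pytest.fixture
def cube_voi():
    """5x5x5 all-masked VOI with reproducible random HU values."""
    rng = np.random.default_rng(42)
    vox = rng.normal(50.0, 20.0, size=(5, 5, 5))
    return NodeVOI(ImageVolume(vox, (1.0, 1.0, 1.0)), np.ones((5, 5, 5), bool))


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny standard-signal cohort reused across integration tests."""
    from nodalrad.cohort import CohortConfig, generate_cohort

    cfg = CohortConfig(n_patients=6, nodes_per_patient_mean=5,
                       nodes_per_patient_sd=2, seed=123)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_backbone():
    from nodalrad.deep import BackboneConfig, build_backbone

    return build_backbone(BackboneConfig(stage_channels=(8, 16, 32), seed=7))
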