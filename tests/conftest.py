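import numpy as np
import pytest

from hipspace.synthetic import default_distributions, build_hip, generate_cohort


@pytest.fixture(scope="session")
def mean_hip_female():
    """Noise-free hip built at the exact female parameter means."""
    params = default_distributions("female").mean_params()
    pelvis, femur = build_hip(params)
    return params, pelvis, femur


@pytest.fixture(scope="session")
def mean_hip_male():
    params = default_distributions("male").mean_params()
    pelvis, femur = build_hip(params)
    return params, pelvis, femur


@pytest.fixture(scope="session")
def small_cohorts():
    """300-sample seeded cohorts per sex with their truth tables."""
    out = {}
    for i, sex in enumerate(("female", "male")):
        meshes, truth = generate_cohort(sex, 300, seed=100 + i)
        out[sex] = (meshes, truth)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
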