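import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import primage as pm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    """Default generator parameters (the programmed study conditions)."""
    return pm.AgingModelParams()


@pytest.fixture(scope="session")
def clean_params():
    """Artifact-free rendering parameters for exactness tests."""
    return pm.AgingModelParams(intensity_noise_sd=0.0, bias_amplitude=0.0,
                               slice_gain_sd=0.0)


@pytest.fixture(scope="session")
def clean_phantom(clean_params):
    """One artifact-free phantom (image + ground truth) at cohort-mean age."""
    gm, wm, csf = pm.trajectory_fractions(clean_params, "female", 9.43)
    spec = pm.PhantomSpec(pm.SubjectRecord("F00", "female", 9.43),
                          gm, wm, csf, 186.7, seed=7)
    img, truth = pm.render_phantom(spec, clean_params)
    return spec, img, truth


@pytest.fixture(scope="session")
def small_cohort(params):
    """A small mixed-sex cohort reused across read-only tests."""
    return pm.generate_cohort(params, n_per_sex=(3, 3), master_seed=42)
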