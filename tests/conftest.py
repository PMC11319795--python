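import numpy as np
import pytest

from echosway.synthetic import CohortSpec, default_group, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study conditions (32 young, 34 old)."""
    return generate_cohort(CohortSpec(seed=20240812))


@pytest.fixture(scope="session")
def small_image_phenotype_kwargs():
    """Reduced image geometry so texture tests stay fast."""
    return dict(image_size=(200, 160), skin_depth_px=20, sat_thickness_px=40)
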