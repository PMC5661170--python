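import numpy as np
import pytest

from wmnet import Bundle, CohortSpec, PhantomSpec, gen_cohort, gen_tensor_phantom


@pytest.fixture(scope="session")
def straight_phantom():
    """One straight bundle along +x through a 40x12x12 grid."""
    centerline = np.array([[0.0, 6.0, 6.0], [40.0, 6.0, 6.0]])
    spec = PhantomSpec(shape=(40, 12, 12),
                       bundles=[Bundle(centerline, radius=2.5)])
    vol, mask = gen_tensor_phantom(spec)
    return spec, vol, mask


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic two-group cohort (21 patients, 25 controls)."""
    return gen_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted group difference."""
    return gen_cohort(CohortSpec(effect_size=0.0, seed=12))
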