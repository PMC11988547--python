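import numpy as np
import pytest

from lungmorph.synthetic import CohortSpec, generate_cohort, render_tile


@pytest.fixture(scope="session")
def small_cohort():
    spec = CohortSpec(n_patients_class1=6, n_patients_class2=6, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def rendered(small_cohort):
    """One rendered tile with ground truth from the first patient."""
    return render_tile(small_cohort[0], n_nuclei=10, seed=21, tile_size=96)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
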