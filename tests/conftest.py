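import numpy as np
import pytest

import cipropk as c


@pytest.fixture(scope="session")
def typical_params() -> c.PKParameters:
    """Published typical two-compartment parameters (adult ICU cohort)."""
    return c.PKParameters(cl=25.4, vc=91.1, vp=164.0, q=91.9)


@pytest.fixture(scope="session")
def ref_model() -> c.PopulationModel:
    return c.reference_model()


@pytest.fixture(scope="session")
def default_cohort():
    """One default 42-subject synthetic cohort plus its hidden truth."""
    dataset, truth = c.generate_cohort(seed=20_260_923)
    return dataset, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast cohort for estimation-path tests (1/6/3 split)."""
    design = c.StudyDesign(group_sizes=(1, 6, 3))
    dataset, truth = c.generate_cohort(design, seed=41)
    return dataset, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort, ref_model):
    dataset, _ = small_cohort
    return c.fit(dataset, ref_model, method="bfgs", compute_rse=False)


def random_params(rng: np.random.Generator) -> c.PKParameters:
    """Physiologically plausible random parameter draw for oracle checks."""
    return c.PKParameters(
        cl=float(rng.uniform(5.0, 60.0)),
        vc=float(rng.uniform(20.0, 200.0)),
        vp=float(rng.uniform(50.0, 400.0)),
        q=float(rng.uniform(10.0, 200.0)),
    )
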