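import numpy as np
import pytest

import epidyn as ed


@pytest.fixture(scope="session")
def parc12():
    return ed.generate_parcellation(12, seed=1)


@pytest.fixture(scope="session")
def sc12(parc12):
    return ed.generate_structural_connectome(12, density=0.4, seed=2,
                                             parcellation=parc12)


@pytest.fixture(scope="session")
def fcg12(parc12):
    return ed.default_gradient(parc12)


@pytest.fixture(scope="session")
def coeffs():
    return ed.default_coefficients()


@pytest.fixture(scope="session")
def truth12(coeffs, fcg12):
    return ed.generate_ground_truth(coeffs, fcg12)


@pytest.fixture(scope="session")
def cohort12(sc12, truth12, coeffs):
    """Six healthy-control pseudo-subjects, 12 regions, 240 frames."""
    spec = ed.SyntheticCohortSpec(n_regions=12, n_subjects_per_group=6, seed=7)
    return ed.generate_cohort(spec, sc12, {"HC": truth12}, coeffs.G)


from epidyn.surrogates import gaussian_random_field  # noqa: E402,F401  (test helper)
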