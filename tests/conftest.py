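import numpy as np
import pytest

import datsbr as d


@pytest.fixture(scope="session")
def clinical_cohort() -> d.CohortTable:
    """Default clinical-like cohort (186 normal, 186 disease), seed 0."""
    return d.sample_cohort(d.clinical_like_spec(seed=0))


@pytest.fixture(scope="session")
def ppmi_cohort() -> d.CohortTable:
    return d.sample_cohort(d.ppmi_like_spec(seed=0))


@pytest.fixture(scope="session")
def sharp_phantom():
    """Noiseless, unblurred default phantom with asymmetric putamen binding."""
    spec = d.default_phantom_spec(
        psf_fwhm=0.0, noise_scale=0.0,
        binding={"putamen_L": 0.5, "putamen_R": 1.5},
    )
    return d.render_phantom(spec)


@pytest.fixture(scope="session")
def blurred_phantom():
    """Noiseless default phantom with a 7-mm PSF."""
    return d.render_phantom(d.default_phantom_spec(psf_fwhm=7.0, noise_scale=0.0))
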