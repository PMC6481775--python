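import numpy as np
import pandas as pd
import pytest

from allohet import AllometricModel, SyntheticConfig
from allohet import synthetic_data as sd
from allohet import phenotype_io as pio
from allohet.config import ACCESSION_FRUIT_COEFFS, ACCESSION_GROWTH_COEFFS


def model_from_coeffs(form, coeffs, fitted_on="accessions"):
    names = "abc"[: len(coeffs)]
    return AllometricModel(
        form=form,
        coefficients=dict(zip(names, coeffs)),
        ci95={k: (v, v) for k, v in zip(names, coeffs)},
        n=0,
        rss=0.0,
        aic=0.0,
        fitted_on=fitted_on,
    )


@pytest.fixture(scope="session")
def growth_model():
    """Reference accession growth allometry g(M) = a*M**(b + c*log10 M)."""
    return model_from_coeffs("power_mass_corrected", ACCESSION_GROWTH_COEFFS)


@pytest.fixture(scope="session")
def fruit_model():
    """Reference accession fruit allometry f(M) = M/(a + b*M + c*M**2)."""
    return model_from_coeffs("inverse_quadratic", ACCESSION_FRUIT_COEFFS)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_accessions=80, n_hybrids=60, n_markers=200, seed=7)


@pytest.fixture(scope="session")
def cohort(small_config):
    """Small synthetic bundle shared across read-only tests."""
    return sd.generate_dataset(small_config)


@pytest.fixture(scope="session")
def cohort_summaries(cohort):
    return pio.summarize_genotypes(cohort["phenotypes"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
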