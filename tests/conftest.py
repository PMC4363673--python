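import numpy as np
import pandas as pd
import pytest

from cordnorm import Cohort, default_config, derive_metrics, generate_cohort


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


@pytest.fixture(scope="session")
def cohort32(default_cfg):
    """One study-sized synthetic cohort (n=32, fixed seed)."""
    return generate_cohort(default_cfg, n=32, seed=7)


@pytest.fixture(scope="session")
def big_cohort(default_cfg):
    """Large cohort for convergence checks against configured moments."""
    return generate_cohort(default_cfg, n=20_000, seed=11)


@pytest.fixture
def tiny_cohort():
    """Hand-written 3-subject cohort with one missing thoracic record."""
    subjects = pd.DataFrame({
        "id": ["a", "b", "c"],
        "sex": ["M", "F", "F"],
        "age": [35.0, 52.0, 61.0],
        "height": [180.0, 165.0, np.nan],
        "weight": [80.0, 62.0, 70.0],
    })
    cord = pd.DataFrame({
        "id": ["a", "a", "b", "b", "c"],
        "level": ["C2-C3", "T9-T10", "C2-C3", "T9-T10", "C2-C3"],
        "tca_mm2": [82.0, 47.0, 76.5, 44.0, 74.0],
        "gm_mm2": [20.0, 11.5, 18.5, 10.5, 18.0],
    })
    covariates = pd.DataFrame({
        "id": ["a", "b"],
        "ticv": [1_550_000.0, 1_350_000.0],
        "ap_vertebra_diameter": [16.0, 15.0],
        "anterior_height": [13.0, 12.0],
        "posterior_height": [12.0, 11.5],
        "middle_vertebra_height": [11.8, 11.0],
    })
    return derive_metrics(Cohort(subjects=subjects, cord=cord,
                                 covariates=covariates))
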