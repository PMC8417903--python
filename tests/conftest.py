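import numpy as np
import pandas as pd
import pytest

from trajclust import data_prep, mlcmm, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny crisp 2-class/2-cluster cohort with full attendance."""
    cfg = synthetic.scenario("small_test", n_subjects=60)
    return synthetic.generate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def crisp_fit_bundle():
    """A crisp 2-class cohort (n = 300) with its fitted MLCMM, shared by the
    classification and prediction tests."""
    cfg = synthetic.scenario("crisp_classes", n_subjects=300)
    cohort, profiles, truth = synthetic.generate_cohort(cfg, seed=13)
    filtered, _ = data_prep.filter_eligible(cohort, require_apoe=True)
    data = mlcmm.MLCMMData.from_cohort(filtered)
    spec = mlcmm.MLCMMSpec(n_classes=2)
    fit = mlcmm.fit(data, spec, n_starts=3, seed=99)
    return dict(cfg=cfg, cohort=cohort, profiles=profiles, truth=truth,
                data=data, spec=spec, fit=fit)


@pytest.fixture()
def toy_subjects():
    """Hand-written baseline table exercising every dichotomisation rule."""
    return pd.DataFrame({
        "subject_id": ["a", "b", "c", "d"],
        "age": [60.0, 70.0, 65.0, 55.0],
        "sex": ["female", "male", "female", "male"],
        "education_level": [1, 2, 3, 1],
        "family_history": ["yes", "no", "yes", "no"],
        "apoe4": ["no", "yes", np.nan, "no"],
        "cdr_global": [0.0, 0.5, 0.0, 0.0],
        "ptau_abeta": [0.030, 0.024, 0.010, np.nan],
        "mta_avg": [1.5, 0.5, 0.0, np.nan],
        "fsd": [2.0, 1.0, 0.0, 3.0],
        "fspv": [1.0, 0.0, 2.0, 0.0],
        "arwmc_bg": [1.0, 0.0, 1.0, 0.0],
        "arwmc_f": [1.0, 1.0, 0.0, 0.0],
        "arwmc_it": [1.0, 0.0, 0.0, 0.0],
        "arwmc_po": [0.0, 1.0, 2.0, 0.0],
        "arwmc_t": [0.0, 0.0, 2.0, 0.0],
        "hv_baseline": [5800.0, 6000.0, 5600.0, 5900.0],
        "vv_baseline": [30000.0, 35000.0, 40000.0, 28000.0],
        "hv_last": [5600.0, 6000.0, np.nan, 5800.0],
        "vv_last": [33000.0, 35000.0, np.nan, 29000.0],
        "t_last_volume": [2.0, 1.0, np.nan, 1.5],
    })
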