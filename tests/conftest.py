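import numpy as np
import pandas as pd
import pytest

from heartbrain.synthetic import CohortConfig, CovariateSpec, ExposureSpec, GwasSimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with one strong exposure, covariates and missingness."""
    config = CohortConfig(
        n_participants=20_000,
        outcome_prevalence_baseline=0.05,
        exposure_specs=[
            ExposureSpec("hypotension", "I95", prevalence=0.10, log_odds=np.log(2.5)),
            ExposureSpec("rheumatic", "I05-I09", prevalence=0.05, log_odds=0.3),
        ],
        covariate_specs=[
            CovariateSpec("age", "continuous", {"mean": 56.5, "sd": 8.1}, log_odds=0.5),
            CovariateSpec("bmi", "continuous", {"mean": 27.4, "sd": 4.8}, log_odds=0.0, missing_rate=0.2),
            CovariateSpec(
                "smoking_status", "categorical",
                {"levels": ["Never", "Previous", "Current"], "probs": [0.55, 0.34, 0.11]},
                log_odds=0.2, risk_level="Current", missing_rate=0.05,
            ),
        ],
        seed=42,
    )
    table, records, truth = simulate_cohort(config)
    return config, table, records, truth


@pytest.fixture()
def planted_gwas_config():
    return GwasSimConfig(
        n_snps_per_side=25,
        n_chromosomes=4,
        chromosome_length=60_000_000,
        n_planted_shared_loci=5,
        planted_offset_max=50_000,
        background_clearance_bp=1_000_000,
        n_nonsignificant_per_side=10,
        seed=7,
    )
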