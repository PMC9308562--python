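import numpy as np
import pandas as pd
import pytest

from multistage import (
    Covariate,
    CovariateDesign,
    CovariateSchema,
    EntryAgeLaw,
    GeneratorConfig,
    WeibullPH,
    generate_cohort,
)


@pytest.fixture(scope="session")
def true_model() -> WeibullPH:
    return WeibullPH(m=5.0, L=100.0)


@pytest.fixture(scope="session")
def diabetes_schema() -> CovariateSchema:
    return CovariateSchema((Covariate("diabetes", ("no", "yes")),))


@pytest.fixture(scope="session")
def diabetes_config(diabetes_schema) -> GeneratorConfig:
    """The reference simulation: n=20,000, m=5, L=100, beta_diabetes=0.5."""
    return GeneratorConfig(
        seed=20220622,
        n_subjects=20_000,
        true_model=WeibullPH(
            m=5.0, L=100.0, beta={"diabetes:yes": 0.5}, schema=diabetes_schema
        ),
        covariate_design=(
            CovariateDesign("diabetes", ("no", "yes"), (0.9, 0.1), {"yes": 0.5}),
        ),
        followup_years=10.0,
    )


@pytest.fixture(scope="session")
def diabetes_cohort(diabetes_config) -> pd.DataFrame:
    return generate_cohort(diabetes_config)


@pytest.fixture(scope="session")
def plain_cohort(true_model) -> pd.DataFrame:
    """No-covariate cohort at the reference truth."""
    return generate_cohort(
        GeneratorConfig(seed=7, n_subjects=20_000, true_model=true_model)
    )


@pytest.fixture(scope="session")
def common_entry_cohort(true_model) -> pd.DataFrame:
    """Everyone enters at exactly age 50 with 30 years of follow-up."""
    cfg = GeneratorConfig(
        seed=11,
        n_subjects=20_000,
        true_model=true_model,
        entry_age_law=EntryAgeLaw(mean=50.0, sd=0.0, lower=50.0, upper=50.0),
        followup_years=30.0,
    )
    return generate_cohort(cfg)
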