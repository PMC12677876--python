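import numpy as np
import pytest

from actimood import (
    ClassifierConfig,
    GeneratorConfig,
    compute_daily_features,
    compute_met_daily,
    generate_cohort,
)

SMALL_SIZES = {
    "ADHD_without_BD": 6,
    "BD_with_ADHD": 5,
    "BD_without_ADHD": 4,
    "OTHER": 8,
}


@pytest.fixture(scope="session")
def small_cohort():
    """23 patients, 4-8 days each: the shared workhorse fixture."""
    cfg = GeneratorConfig(
        group_sizes=dict(SMALL_SIZES), days_per_patient=(4, 8), seed=7
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    """(daily_features, met_daily, patients) for the small cohort."""
    feats = compute_daily_features(small_cohort.epochs)
    met_daily = compute_met_daily(small_cohort.met)
    return feats, met_daily, small_cohort.patients


@pytest.fixture(scope="session")
def fast_clf_config():
    return ClassifierConfig(
        model_menu=("logistic_regression",), include_ensemble=False, seed=0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
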