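import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ctdip import ItemScores, SyntheticCohortConfig, generate_cohort
from ctdip.datasets import worked_example_scores

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def worked_case() -> pd.DataFrame:
    """The published four-pathologist worked-example score table."""
    return worked_example_scores()


@pytest.fixture
def worked_case_items(worked_case) -> dict[str, ItemScores]:
    """Same case as per-rater ItemScores objects, keyed by rater."""
    return {
        row.rater_id: ItemScores(
            ff=row.ff, smh=row.smh, cip=row.cip, dpvc=row.dpvc,
            fat=row.fat, plasm=row.plasm, lygc=row.lygc, af=row.af,
        )
        for row in worked_case.itertuples()
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-case, 4-rater synthetic cohort shared across tests."""
    cfg = SyntheticCohortConfig.default(n_cases=60, seed=17)
    return generate_cohort(cfg)
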