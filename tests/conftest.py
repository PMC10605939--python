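import pytest

from mmr_vclass.fixtures import load_fixture_bundle
from mmr_vclass.pipeline import run_fixture_analysis, run_synthetic_pipeline
from mmr_vclass.synthetic import ScenarioConfig


@pytest.fixture(scope="session")
def cohort():
    """The frozen curated cohort (full bundle)."""
    return load_fixture_bundle("all")


@pytest.fixture(scope="session")
def fixture_analysis(cohort):
    """(results, summary) of the classifier stack over the curated cohort."""
    return run_fixture_analysis(cohort)


@pytest.fixture(scope="session")
def synthetic_run():
    """Default strong-signal synthetic cohort pushed through the pipeline."""
    return run_synthetic_pipeline(ScenarioConfig(seed=1))
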