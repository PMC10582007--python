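import pytest
from hypothesis import settings

from neoscreen.fixtures import generate_fixtures
from neoscreen.pipeline import run_pipeline

settings.register_profile("default", derandomize=True, max_examples=60,
                          database=None)
settings.load_profile("default")

FIXTURE_SEED = 17


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Seeded synthetic input bundle with 6 planted positives."""
    out = tmp_path_factory.mktemp("fixtures")
    return generate_fixtures(
        FIXTURE_SEED, out, n_proteins=8, n_variants=24, fraction_planted=0.25
    )


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    return run_pipeline(bundle.make_config(), write_outputs=True)
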