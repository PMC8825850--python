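import pytest
from hypothesis import HealthCheck, settings

from mitocbe import TargetSpec, load_fasta
from mitocbe.pipeline import make_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    make_fixture(d, seed=FIXTURE_SEED)
    return d


@pytest.fixture(scope="session")
def fixture_genome(fixture_dir):
    return load_fasta(fixture_dir / "genome.fa")


@pytest.fixture(scope="session")
def fixture_spec(fixture_dir):
    return TargetSpec.from_yaml(fixture_dir / "target.yaml")
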