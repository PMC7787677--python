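import pytest
from hypothesis import HealthCheck, settings

from kinetrace import (
    Store,
    SyntheticProtocol,
    run_pipeline,
    simulate_respirometry,
    write_raw,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def protocol():
    """Noise-free 6-step ADP titration with known kinetics."""
    return SyntheticProtocol()


@pytest.fixture
def clean_experiment(protocol):
    return simulate_respirometry(protocol)


@pytest.fixture
def raw_file(tmp_path, clean_experiment):
    data, _ = clean_experiment
    return write_raw(data, tmp_path / "exp.tsv")


@pytest.fixture
def store():
    with Store(":memory:") as s:
        s.init_schema()
        yield s


@pytest.fixture
def analyzed_store(raw_file):
    """Store holding the fully analyzed noise-free titration."""
    with Store(":memory:") as s:
        report = run_pipeline(raw_file, s)
        assert report.ok, report.stages
        yield s, report.experiment_id
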