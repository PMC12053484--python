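import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from crasskit.simulate import CommunitySpec, simulate_community, \
    write_fixture


@pytest.fixture(scope="session")
def default_spec():
    return CommunitySpec(seed=1)


@pytest.fixture(scope="session")
def default_bundle(default_spec):
    return simulate_community(default_spec)


@pytest.fixture(scope="session")
def fixture_dir(default_bundle, tmp_path_factory):
    """Default community written as a fixture directory (with reads)."""
    d = tmp_path_factory.mktemp("community")
    write_fixture(default_bundle, str(d), with_reads=True)
    return str(d)


@pytest.fixture(scope="session")
def pipeline_out(fixture_dir, tmp_path_factory):
    """One full CLI run-all over the default fixture, shared by the
    end-to-end assertions. Returns (outdir, elapsed seconds)."""
    import time
    from click.testing import CliRunner
    from crasskit.cli import main
    out = tmp_path_factory.mktemp("pipeline")
    t0 = time.time()
    result = CliRunner().invoke(
        main, ["run-all", "--fixture", fixture_dir, "--outdir", str(out)],
        catch_exceptions=False)
    elapsed = time.time() - t0
    assert result.exit_code == 0, result.output
    return str(out), elapsed


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
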