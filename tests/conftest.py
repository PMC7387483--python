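import logging

import pytest

from lcampscreen.fixtures import FixtureSpec, make_fixture_proteome
from lcampscreen.motif import load_pwm
from lcampscreen.pipeline import ScreenConfig, run_funnel

logging.getLogger("lcampscreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_config():
    return ScreenConfig()


@pytest.fixture(scope="session")
def fixture_proteome(default_config):
    """Synthetic proteome: 5 planted precursors + 7 stage-labelled decoys."""
    records, truth = make_fixture_proteome(FixtureSpec(n_planted=5, seed=0), default_config)
    return records, truth


@pytest.fixture(scope="session")
def funnel_result(fixture_proteome, default_config):
    records, _ = fixture_proteome
    return run_funnel(records, default_config)


@pytest.fixture(scope="session")
def default_pwm():
    from importlib import resources

    ref = resources.files("lcampscreen.data") / "nfkb_synthetic_counts.txt"
    with resources.as_file(ref) as path:
        return load_pwm(path)
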