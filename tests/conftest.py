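import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ecghmm.filters import IcbsFilterSpec
from ecghmm.pipeline import PipelineConfig, align_filtered, segment_record
from ecghmm.synthetic import NoiseSettings, make_plan, make_rhythm


@pytest.fixture(scope="session")
def default_spec() -> IcbsFilterSpec:
    return IcbsFilterSpec()


@pytest.fixture(scope="session")
def clean_rhythm():
    """60 noise-free mixed beats with ground truth (session-wide fixture)."""
    plan = make_plan(60, pvc_rate=0.1, apc_rate=0.1, seed=13,
                     noise=NoiseSettings.none())
    return make_rhythm(plan, 400.0)


@pytest.fixture(scope="session")
def clean_stream(clean_rhythm):
    cfg = PipelineConfig()
    filtered = align_filtered(clean_rhythm, cfg.filter_spec)
    return segment_record(filtered, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
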