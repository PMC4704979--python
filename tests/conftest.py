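import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def protocol_program():
    from wmtrain import PROTOCOL_PROGRAM

    return PROTOCOL_PROGRAM


@pytest.fixture
def protocol_thresholds():
    from wmtrain import PROTOCOL_THRESHOLDS

    return PROTOCOL_THRESHOLDS


@pytest.fixture
def store(tmp_path):
    from wmtrain import Store

    with Store(tmp_path / "store") as s:
        yield s
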