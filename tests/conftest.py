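import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

# arviz emits a refactor FutureWarning on import; irrelevant to the tests
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture()
def demo_outdir(tmp_path):
    return tmp_path / "demo"
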