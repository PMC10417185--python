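import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from colcea.synthetic import make_full_config


@pytest.fixture(scope="session")
def stage2_config():
    return make_full_config("high_risk_stage_ii", seed=1)


@pytest.fixture(scope="session")
def stage3_config():
    return make_full_config("stage_iii", seed=1)


@pytest.fixture(scope="session")
def stage2_report(stage2_config):
    from colcea.report import run_base_case

    return run_base_case(stage2_config)


@pytest.fixture(scope="session")
def stage3_report(stage3_config):
    from colcea.report import run_base_case

    return run_base_case(stage3_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
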