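import sys
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from riscprof.synthetic_data import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A modest synthetic study shared by read-only tests (seed 11)."""
    return generate_study(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_results(small_study):
    from riscprof.pipeline import run_pipeline

    return run_pipeline(*small_study[:5])
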