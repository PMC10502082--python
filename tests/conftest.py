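import numpy as np
import pytest

from zganet.core_model import DEFAULT_FIT_GENOTYPES, build_core_model
from zganet.mini_models import InputCurves


@pytest.fixture(scope="session")
def default_model():
    return build_core_model("default")


@pytest.fixture(scope="session")
def input_curves(default_model):
    """Protein input curves for the seven fit conditions (shared: simulating
    the core model once per session keeps the suite fast)."""
    return InputCurves.from_core(default_model, DEFAULT_FIT_GENOTYPES)


@pytest.fixture(scope="session")
def obs_times():
    return np.linspace(2.5, 6.0, 8)
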