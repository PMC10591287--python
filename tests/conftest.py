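import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

import freeview as fv


@pytest.fixture(scope="session")
def small_session():
    """A small unmodulated synthetic session shared across tests."""
    return fv.generate_session(seed=11, n_scenes=6, n_repeats=2, n_units=8)


@pytest.fixture(scope="session")
def modulated_session():
    """A session with order-dependent gain 0.8 on later fixations."""
    mod = fv.ModulationSpec(order_gain={1: 1.0, 2: 0.8},
                            within_fixation_decay=0.9)
    return fv.generate_session(seed=12, n_scenes=12, n_repeats=4, n_units=20,
                               modulation=mod)
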