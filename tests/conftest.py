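import numpy as np
import pytest

from twostate import ModelParams


@pytest.fixture
def reference_params():
    """Size ratio 4 with moderate switching penalty and solvent tension.

    This parameter set sits in the regime where the state distribution jumps
    discontinuously and two phases coexist, exercising every solver branch.
    """
    return ModelParams(xi=4.0, lam=1.5, chi=1.2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
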