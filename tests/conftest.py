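import numpy as np
import pytest

from cvsteer.model import (GatedModelParams, build_bead_model,
                           build_cv_space_model)


@pytest.fixture(scope="session")
def model():
    """Default gated two-basin CV-space model."""
    return build_cv_space_model()


@pytest.fixture(scope="session")
def bead_model():
    return build_bead_model()


@pytest.fixture(scope="session")
def refs(model):
    return model.refs


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def gates_off_model():
    """Model with all gate and coupling amplitudes zeroed (and the
    gate-compensating basin calibrations, which exist only to cancel
    gate-induced distortion, zeroed with them)."""
    return build_cv_space_model(GatedModelParams(
        A_block=0.0, A_lock=0.0, A_sb=0.0, A_rot=0.0, strain_coupling=0.0,
        cal_d6_closed=0.0, cal_d6_open=0.0, cal_d2_closed=0.0,
        cal_chi_closed=0.0, cal_chi_open=0.0))
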