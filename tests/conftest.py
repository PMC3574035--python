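import numpy as np
import pytest

from cholsim import Model


@pytest.fixture(scope="session")
def default_model() -> Model:
    return Model.default()


@pytest.fixture(scope="session")
def calibrated_model() -> Model:
    """Calibrated baseline; computed once per session (deterministic)."""
    return Model.calibrated()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20120130)


@pytest.fixture(scope="session")
def absorption_results(calibrated_model):
    """Ageing-absorption deltas for every endpoint label, computed once."""
    from cholsim import ageing_absorption

    return {f: ageing_absorption(calibrated_model, final_fraction=f,
                                 readout_steady=False)
            for f in (0.5, 0.6, 0.7, 0.8)}


@pytest.fixture(scope="session")
def receptor_results(calibrated_model):
    """Ageing-receptor deltas for every endpoint, computed once."""
    from cholsim import ageing_receptor

    return {r: ageing_receptor(calibrated_model, final_receptors=r,
                               readout_steady=False)
            for r in (90.0, 80.0, 70.0, 60.0, 50.0)}
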