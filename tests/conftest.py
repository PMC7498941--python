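import numpy as np
import pytest

from netthin.synth import SessionConfig, generate_session, generate_templates


@pytest.fixture(scope="session")
def session_config() -> SessionConfig:
    return SessionConfig(seed=11)


@pytest.fixture(scope="session")
def templates(session_config):
    return generate_templates(session_config)


@pytest.fixture(scope="session")
def session(templates, session_config):
    """One default synthetic session: (bold, motion, tissues, truth)."""
    return generate_session(templates, session_config)


@pytest.fixture(scope="session")
def noiseless_session(templates, session_config):
    import dataclasses

    cfg = dataclasses.replace(session_config, noise_sd=0.0, nuisance_amplitude=0.0)
    return generate_session(templates, cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
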