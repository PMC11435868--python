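import dataclasses

import pytest

from fmgkit import (
    SessionSpec,
    build_all_frames,
    default_gestures,
    generate_session,
)


def noiseless_spec(**overrides) -> SessionSpec:
    """A deterministic spec: no noise, offsets, drift or onset ramp."""
    gestures = tuple(
        dataclasses.replace(g, onset_ramp_s=0.0) for g in default_gestures()
    )
    base = dict(
        gestures=gestures,
        noise_sd=0.0,
        trial_offset_sd=0.0,
        drift_slope=0.0,
        seed=0,
    )
    base.update(overrides)
    return SessionSpec(**base)


@pytest.fixture(scope="session")
def default_spec() -> SessionSpec:
    return SessionSpec(seed=1)


@pytest.fixture(scope="session")
def session_streams(default_spec):
    return generate_session(default_spec)


@pytest.fixture(scope="session")
def all_frames(session_streams):
    return build_all_frames(session_streams)


@pytest.fixture(scope="session")
def noiseless_streams():
    return generate_session(noiseless_spec())
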