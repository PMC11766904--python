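import numpy as np
import pytest

from eegdem.io import CANONICAL_CHANNELS, REFERENCE_CHANNELS, Recording
from eegdem.synth import CohortSpec, default_profiles, generate_subject


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def short_spec():
    # 90 s is enough for three 30 s epochs; artifacts off for clean fixtures
    return CohortSpec(n_per_group={"AD": 1, "FTD": 1, "CN": 1},
                      duration_s=90.0, seed=42,
                      artifact_rate=0.0, blink_rate=0.0)


@pytest.fixture(scope="session")
def cn_subject(profiles, short_spec):
    return generate_subject(profiles["CN"], short_spec, 0, "sub-cn", "CN")


@pytest.fixture(scope="session")
def ad_subject(profiles, short_spec):
    return generate_subject(profiles["AD"], short_spec, 1, "sub-ad", "AD")


def make_recording(data, fs=500.0, subject_id="sub-x", group="CN",
                   with_refs=True):
    """Recording with canonical channels from a (19[+2], n) array."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    names = list(CANONICAL_CHANNELS)
    refs = []
    if with_refs:
        names += list(REFERENCE_CHANNELS)
        refs = list(REFERENCE_CHANNELS)
    assert data.shape[0] == len(names)
    return Recording(subject_id, group, data, fs, names, refs)


@pytest.fixture
def constant_recording():
    """Scalp constant 5 µV, A1 = 2, A2 = 4 (re-referencing arithmetic)."""
    n = 2500
    data = np.vstack([np.full((19, n), 5.0),
                      np.full((1, n), 2.0),
                      np.full((1, n), 4.0)])
    return make_recording(data)
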