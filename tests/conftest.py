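import numpy as np
import pytest

from emgadapt.data import EmgTrial, WindowSpec
from emgadapt.synthetic import (
    BenchmarkConfig,
    generate_shift_model,
    generate_subject_profile,
    synthesize_trial,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def profile():
    return generate_subject_profile(seed=3)


@pytest.fixture(scope="session")
def identity_shift(profile):
    return generate_shift_model(0, subject=1, day=1, s=1.0)


@pytest.fixture(scope="session")
def one_trial(profile, identity_shift):
    """A standard 7-s, 7-channel trial at 1500 Hz."""
    return synthesize_trial(
        profile, identity_shift, motion=1, day=1, trial_index=1,
        master_seed=3,
    )


def make_noise_trial(rng, n_channels=7, duration_s=7.0, rate=1500.0,
                     scale=30.0, **kwargs):
    """A white-noise trial for geometry-level tests (fast, no filtering)."""
    n = int(duration_s * rate)
    defaults = dict(motion=1, trial_index=1, day=1, subject="1")
    defaults.update(kwargs)
    from emgadapt.data import DEFAULT_CHANNEL_NAMES

    return EmgTrial(
        samples=rng.normal(scale=scale, size=(n_channels, n)),
        sampling_rate=rate,
        channel_names=DEFAULT_CHANNEL_NAMES[:n_channels],
        **defaults,
    )


@pytest.fixture()
def noise_trial(rng):
    return make_noise_trial(rng)


def clustered_data(rng, n_classes=3, n_per_class=40, n_dims=6, spread=1.0,
                   separation=4.0):
    """Gaussian class blobs with controllable separation."""
    X, y = [], []
    for c in range(n_classes):
        centre = rng.normal(scale=separation, size=n_dims)
        X.append(centre + rng.normal(scale=spread, size=(n_per_class, n_dims)))
        y.append(np.full(n_per_class, c))
    return np.concatenate(X), np.concatenate(y)
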