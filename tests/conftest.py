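import numpy as np
import pytest

from mirrorgame import features_dyad
from mirrorgame.synthetic_data import FollowerParams, Trajectory, simulate_follower


def sine_trajectory(freq, duration=30.0, rate=40.0, amp=0.3, center=0.5,
                    phase=0.0, condition="solo"):
    t = np.arange(int(duration * rate) + 1) / rate
    x = center + amp * np.sin(2 * np.pi * freq * t + phase)
    return Trajectory(t=t, x=x, rate=rate, condition=condition)


@pytest.fixture(scope="session")
def delayed_follower_pair():
    """0.5 Hz sinusoidal leader with a noiseless high-gain follower delayed
    by 0.25 s: relative phase should approach 2*pi*0.5*0.25 = pi/4."""
    leader = sine_trajectory(0.5, duration=30.0, rate=40.0, condition="leader")
    follower = simulate_follower(
        leader, FollowerParams(lag=0.25, gain=200.0, noise_sd=0.0), seed=0)
    return leader, follower


@pytest.fixture(scope="session")
def delayed_coherence_field(delayed_follower_pair):
    leader, follower = delayed_follower_pair
    field = features_dyad.wavelet_coherence(leader, follower)
    return features_dyad.significance_mask(field, n_surrogates=80, seed=1)
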