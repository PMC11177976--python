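import numpy as np
import pytest

from chirpic import ChirpTrainSpec, make_chirp_sequence
from chirpic.frontend import RateFunction

FS = 100_000.0


@pytest.fixture
def const_rate():
    """Factory for constant-rate functions (steady-state closed-form checks)."""

    def make(rate: float, dur: float = 0.2, fs: float = 20_000.0) -> RateFunction:
        return RateFunction(np.full(int(round(dur * fs)), rate), fs)

    return make


@pytest.fixture(scope="session")
def chirp_battery():
    """A reduced chirp sequence shared by the mechanism tests.

    8 presentations per velocity condition keep the sequence short (~6 s of
    audio) while the condition averages remain stable.
    """
    spec = ChirpTrainSpec(n_reps=8, seed=3)
    wave, events = make_chirp_sequence(spec, FS)
    return wave, events


def rvf_aggregate_bias(curve, max_speed=3.17):
    """Summed up-minus-down rate difference over low speeds (direction sign)."""
    lookup = dict(zip(curve.x, curve.rate))
    speeds = sorted({abs(v) for v in curve.x if abs(v) <= max_speed})
    return sum(lookup[s] - lookup[-s] for s in speeds)
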