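import numpy as np
import pytest

from flockescape import PigeonState, PredatorState, SimConfig


@pytest.fixture
def cfg() -> SimConfig:
    return SimConfig(n_pigeons=10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_pigeon(i=0, pos=(0.0, 0.0), heading=0.0, speed=18.0, cruise=18.0,
                tendency=0.0, clock=0.0, manoeuvre=None) -> PigeonState:
    return PigeonState(id=i, position=np.asarray(pos, dtype=float),
                       heading=heading, speed=speed, cruise_speed=cruise,
                       escape_tendency=tendency, reaction_clock=clock,
                       manoeuvre=manoeuvre)


def make_predator(pos=(0.0, 0.0), heading=0.0, speed=20.0, phase="pursuit",
                  clock=30.0) -> PredatorState:
    return PredatorState(position=np.asarray(pos, dtype=float), heading=heading,
                         speed=speed, phase=phase, phase_clock=clock)


@pytest.fixture
def line_flock():
    """Ten birds on a vertical line, 2 m apart, all flying along +x."""
    return [make_pigeon(i, (0.0, 2.0 * i)) for i in range(10)]
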