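import numpy as np
import pytest

from colonyca.params import ModelParams, reference_params
from colonyca.state import AGE_UNDEFINED, CellState, SimulationState


@pytest.fixture
def small_params() -> ModelParams:
    """A fast, permissive parameter set for unit tests."""
    return ModelParams(N=16, P=1.0, S=10.0, A=3, O=0.1, D=0.4, G=2,
                       Qlim=50.0, Olim1=20.0, Olim2=60.0, L=21,
                       max_generations=200)


@pytest.fixture
def fig_params() -> ModelParams:
    """Reference rates with the tuned sensitivity thresholds."""
    return reference_params(1000.0, 100.0, 220.0, L=351,
                            max_generations=2000)


def make_state(params: ModelParams, entries: dict[int, tuple],
               quorum=None, odor: float = 0.0,
               generation: int = 0) -> SimulationState:
    """Build a state from {site: (state, thickness[, age])} entries."""
    s = SimulationState.empty(params.L)
    s.generation = generation
    s.odor = float(odor)
    if quorum is not None:
        s.quorum[:] = quorum
    for i, entry in entries.items():
        state, thickness = entry[0], entry[1]
        s.state[i] = state
        s.thickness[i] = thickness
        if len(entry) > 2:
            s.age[i] = entry[2]
        elif state == CellState.S2_EARLY_STATIONARY:
            s.age[i] = 0
    return s


def random_state(rng: np.random.Generator, params: ModelParams) -> SimulationState:
    """A random well-formed state, biased to put signal levels near the
    thresholds so every transition branch gets exercised."""
    L = params.L
    s = SimulationState.empty(L)
    states = rng.choice(
        [int(c) for c in CellState],
        size=L, p=[0.3, 0.25, 0.2, 0.15, 0.1])
    thickness = rng.integers(1, params.N + 1, size=L)
    # bias some sites to exactly N to exercise the thickness triggers
    at_cap = rng.random(L) < 0.2
    thickness[at_cap] = params.N
    s.state[:] = states
    s.thickness[:] = np.where(states == int(CellState.EMPTY), 0, thickness)
    s2 = states == int(CellState.S2_EARLY_STATIONARY)
    s.age[:] = np.where(s2, rng.integers(0, params.A + 2, size=L),
                        AGE_UNDEFINED)
    s.quorum[:] = rng.uniform(0, 2 * params.Qlim, size=L)
    # exact threshold hits now and then
    s.quorum[rng.random(L) < 0.1] = params.Qlim
    s.odor = float(rng.choice(
        [0.0, 0.5 * params.Olim1, params.Olim1,
         0.5 * (params.Olim1 + params.Olim2), params.Olim2,
         1.5 * params.Olim2]))
    s.validate(params)
    return s
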