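"""The automaton itself: the four-step generation loop.

Each generation applies, in order,

1. **state evaluation** — every occupied site changes state according to
   its age (if defined) and the quorum/odor levels, all decisions taken
   against the same pre-step snapshot (synchronous update);
2. **division and migration** — growing sites double in thickness (capped
   at ``N``); one daughter migrates into each adjacent empty site unless a
   diffusible-signal limitation blocks the move;
3. **signal production** — growing and early-stationary sites add quorum
   locally, mature sites add odor to the global pool;
4. **quorum diffusion** — ``G`` nested iterations, each moving a fraction
   ``D`` of every pairwise concentration difference down the gradient.

The model is fully deterministic: identical parameters and inoculum give
bit-identical traces.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import ConfigError, ValidationError
from .params import ModelParams
from .state import (AGE_UNDEFINED, CellState, SimulationState,
                    SimulationTrace, Snapshot)

log = logging.getLogger(__name__)

_EMPTY = int(CellState.EMPTY)
_S1 = int(CellState.S1_EXPONENTIAL)
_S2 = int(CellState.S2_EARLY_STATIONARY)
_S3 = int(CellState.S3_MATURE_STATIONARY)
_S4 = int(CellState.S4_REFRACTORY)


def evaluate_states(state: SimulationState,
                    params: ModelParams) -> SimulationState:
    """Step 1: re-evaluate every site's cell state.

    Only ``state``/``age`` change; thickness and signals are untouched.
    Transition precedence per occupied site (all tested against the
    pre-step snapshot):

    a. growing or early-stationary cells with odor >= ``Olim1`` turn
       refractory (odor outranks the quorum trigger: refractory cells no
       longer respond to quorum, so co-occurring triggers must reactivate);
    b. growing cells with local quorum >= ``Qlim`` or thickness at ``N``
       enter early stationary phase with age 0;
    c. early-stationary cells mature once age >= ``A``; otherwise their
       age advances by one;
    d. refractory cells mature at odor >= ``Olim2`` or thickness ``N``;
    e. mature cells are absorbing; empty sites never change here.
    """
    state.validate(params)
    st = state.state
    new_st = st.copy()
    new_age = state.age.copy()
    odor_high1 = state.odor >= params.Olim1
    odor_high2 = state.odor >= params.Olim2

    is_s1 = st == _S1
    is_s2 = st == _S2
    is_s4 = st == _S4

    # (a) odor-triggered refractory growth, checked first
    to_s4 = (is_s1 | is_s2) & odor_high1
    # (b) quorum / thickness arrest of exponential growth
    to_s2 = is_s1 & ~to_s4 & ((state.quorum >= params.Qlim)
                              | (state.thickness == params.N))
    # (c) maturation of early-stationary sites after the production window
    s2_stays = is_s2 & ~to_s4
    matures = s2_stays & (state.age >= params.A)
    ages = s2_stays & ~matures
    # (d) final arrest of refractory growth
    s4_done = is_s4 & (odor_high2 | (state.thickness == params.N))

    new_st[to_s4] = _S4
    new_age[to_s4] = AGE_UNDEFINED
    new_st[to_s2] = _S2
    new_age[to_s2] = 0
    new_st[matures] = _S3
    new_age[matures] = AGE_UNDEFINED
    new_age[ages] += 1
    new_st[s4_done] = _S3

    return SimulationState(state.generation, state.thickness.copy(), new_st,
                           new_age, state.quorum.copy(), state.odor)


def divide_and_migrate(state: SimulationState,
                       params: ModelParams) -> SimulationState:
    """Step 2: division in growing sites, then colonization of empty
    neighbors.

    Growing sites (exponential or refractory) double, capped at ``N``.
    Every empty site adjacent to at least one growing site then receives
    exactly one daughter bacterium and adopts the colonizer's state,
    unless diffusible signals forbid it: a quorum-sensitive (exponential)
    colonizer is blocked when the target site's quorum is already at
    ``Qlim``; a refractory colonizer ignores quorum but is blocked once
    odor reaches ``Olim2``.  A sole eligible colonizer donates the
    daughter and loses one bacterium (never dropping below thickness 1).
    When both neighbors are eligible — two fronts meeting over one empty
    site — the site still gains exactly one bacterium in the colonizers'
    state (the two fronts necessarily share it: refractory and
    exponential cells never coexist, because the odor trigger is global),
    and neither donor is charged; charging one side would break the
    left-right symmetry a symmetric dish must keep.
    """
    st = state.state
    L = state.L
    growing = (st == _S1) | (st == _S4)

    new_t = state.thickness.copy()
    new_t[growing] = np.minimum(2 * new_t[growing], params.N)

    empty = st == _EMPTY
    odor_blocks_s4 = state.odor >= params.Olim2
    quorum_blocks = state.quorum >= params.Qlim

    def eligible_from(offset: int) -> np.ndarray:
        """Empty sites whose neighbor at `offset` may colonize them."""
        neigh_growing = np.zeros(L, dtype=bool)
        neigh_s1 = np.zeros(L, dtype=bool)
        if offset == -1:
            neigh_growing[1:] = growing[:-1]
            neigh_s1[1:] = st[:-1] == _S1
        else:
            neigh_growing[:-1] = growing[1:]
            neigh_s1[:-1] = st[1:] == _S1
        allowed = np.where(neigh_s1, ~quorum_blocks, not odor_blocks_s4)
        return empty & neigh_growing & allowed

    left_ok = eligible_from(-1)
    right_ok = eligible_from(+1)
    from_left = left_ok            # state inherited from the left when tied
    from_right = right_ok & ~left_ok
    # exports charged only to sole donors: a two-sided tie charges neither
    exports = np.zeros(L, dtype=np.int64)
    np.add.at(exports, np.flatnonzero(left_ok & ~right_ok) - 1, 1)
    np.add.at(exports, np.flatnonzero(right_ok & ~left_ok) + 1, 1)

    new_st = st.copy()
    new_t[from_left] = 1
    new_st[from_left] = st[np.flatnonzero(from_left) - 1]
    new_t[from_right] = 1
    new_st[from_right] = st[np.flatnonzero(from_right) + 1]

    donors = exports > 0
    new_t[donors] = np.maximum(new_t[donors] - exports[donors], 1)

    return SimulationState(state.generation, new_t, new_st, state.age.copy(),
                           state.quorum.copy(), state.odor)


def produce_signals(state: SimulationState,
                    params: ModelParams) -> SimulationState:
    """Step 3: signal production.

    Exponential sites add ``P * thickness`` quorum units locally;
    early-stationary sites add ``S * P * thickness``; mature sites add
    ``O * thickness`` odor units to the single global pool.  Refractory
    and empty sites produce nothing, and neither signal decays.
    """
    st = state.state
    quorum = state.quorum.copy()
    is_s1 = st == _S1
    is_s2 = st == _S2
    quorum[is_s1] += params.P * state.thickness[is_s1]
    quorum[is_s2] += params.S * params.P * state.thickness[is_s2]
    odor = state.odor + params.O * float(
        state.thickness[st == _S3].sum())
    return SimulationState(state.generation, state.thickness.copy(),
                           st.copy(), state.age.copy(), quorum, odor)


def diffuse_quorum(quorum: np.ndarray, params: ModelParams) -> np.ndarray:
    """Step 4: ``G`` iterations of pairwise gradient exchange.

    Per iteration, every adjacent pair exchanges a flux
    ``D * (q_i - q_{i+1})`` from the higher to the lower site; all fluxes
    are computed from the iteration's starting field and applied at once.
    Dish walls are zero-flux (a Petri-dish wall neither absorbs nor
    supplies signal), so total quorum is conserved to floating tolerance.

    The two per-site contributions are accumulated before being applied
    (each site receives ``D*(q[i-1]-q[i]) + D*(q[i+1]-q[i])``); since
    floating addition is commutative, a mirror-symmetric field stays
    bit-exactly symmetric.
    """
    if not 0.0 <= params.D <= 0.5:
        raise ConfigError(f"D: must lie in [0, 0.5], got {params.D}")
    q = np.asarray(quorum, dtype=np.float64).copy()
    D = params.D
    for _ in range(params.G):
        inc = np.zeros_like(q)
        inc[1:] += D * (q[:-1] - q[1:])    # from the left neighbor
        inc[:-1] += D * (q[1:] - q[:-1])   # from the right neighbor
        q += inc
    return q


def step_generation(state: SimulationState,
                    params: ModelParams) -> SimulationState:
    """Advance the dish by one full generation (steps 1-4 in order)."""
    s = evaluate_states(state, params)
    s = divide_and_migrate(s, params)
    s = produce_signals(s, params)
    s.quorum = diffuse_quorum(s.quorum, params)
    s.generation += 1
    return s


def run_simulation(inoculum: SimulationState,
                   params: ModelParams) -> SimulationTrace:
    """Iterate generations until colony development finishes.

    Development is finished when every occupied site is mature-stationary
    (the absorbing state: nothing can change afterwards); the generation
    at which this first holds is recorded as ``terminated_at``.  If
    ``max_generations`` elapse first, the trace is returned unterminated
    (``terminated_at is None``) — a flag, not an error.
    """
    if inoculum.L != params.L:
        raise ValidationError(
            f"inoculum: length {inoculum.L} != configured lattice L={params.L}")
    inoculum.validate(params)
    if inoculum.extent() == 0:
        raise ValidationError("inoculum: no occupied site")

    log.info("run: params=%s", params.to_dict())
    state = inoculum.copy()
    trace = SimulationTrace(params=params)

    def record(s: SimulationState) -> None:
        trace.snapshots.append(Snapshot.of(s))
        trace.extent_series.append(s.extent())
        trace.biomass_series.append(s.biomass())
        trace.odor_series.append(float(s.odor))

    record(state)
    if state.all_mature():
        trace.terminated_at = state.generation
        return trace
    while state.generation < params.max_generations:
        state = step_generation(state, params)
        record(state)
        if state.all_mature():
            trace.terminated_at = state.generation
            break
    log.info("run: %d generations, terminated_at=%s",
             trace.generations, trace.terminated_at)
    return trace
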