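"""Naive, obviously-correct transcription of one automaton generation.

Straight-line Python with explicit loops and no vectorization: each of
the four steps is written directly from its verbal description.  Used as
an independent oracle against the optimized implementation — it must
stay free of any code shared with colonyca.automaton.
"""

from __future__ import annotations

from colonyca.params import ModelParams
from colonyca.state import AGE_UNDEFINED, SimulationState

EMPTY, S1, S2, S3, S4 = 0, 1, 2, 3, 4


def naive_evaluate(state: SimulationState, params: ModelParams) -> SimulationState:
    out = state.copy()
    for i in range(state.L):
        st = int(state.state[i])
        if st == EMPTY or st == S3:
            continue
        if st in (S1, S2) and state.odor >= params.Olim1:
            out.state[i] = S4
            out.age[i] = AGE_UNDEFINED
        elif st == S1 and (state.quorum[i] >= params.Qlim
                           or state.thickness[i] == params.N):
            out.state[i] = S2
            out.age[i] = 0
        elif st == S2:
            if state.age[i] >= params.A:
                out.state[i] = S3
                out.age[i] = AGE_UNDEFINED
            else:
                out.age[i] = state.age[i] + 1
        elif st == S4 and (state.odor >= params.Olim2
                           or state.thickness[i] == params.N):
            out.state[i] = S3
    return out


def naive_divide_and_migrate(state: SimulationState,
                             params: ModelParams) -> SimulationState:
    out = state.copy()
    growing = [int(s) in (S1, S4) for s in state.state]
    for i in range(state.L):
        if growing[i]:
            out.thickness[i] = min(2 * int(state.thickness[i]), params.N)

    def may_colonize(donor: int, target: int) -> bool:
        if not growing[donor]:
            return False
        if int(state.state[donor]) == S1:
            return state.quorum[target] < params.Qlim
        return state.odor < params.Olim2  # refractory donor

    exports = [0] * state.L
    for i in range(state.L):
        if int(state.state[i]) != EMPTY:
            continue
        left_ok = i - 1 >= 0 and may_colonize(i - 1, i)
        right_ok = i + 1 < state.L and may_colonize(i + 1, i)
        if left_ok or right_ok:
            donor = i - 1 if left_ok else i + 1
            out.thickness[i] = 1
            out.state[i] = state.state[donor]
            if left_ok != right_ok:      # a two-sided tie charges neither
                exports[donor] += 1
    for i in range(state.L):
        if exports[i]:
            out.thickness[i] = max(int(out.thickness[i]) - exports[i], 1)
    return out


def naive_produce(state: SimulationState, params: ModelParams) -> SimulationState:
    out = state.copy()
    mature_total = 0  # odor reflects the total over all mature cells
    for i in range(state.L):
        st = int(state.state[i])
        if st == S1:
            out.quorum[i] += params.P * int(state.thickness[i])
        elif st == S2:
            out.quorum[i] += params.S * params.P * int(state.thickness[i])
        elif st == S3:
            mature_total += int(state.thickness[i])
    out.odor += params.O * mature_total
    return out


def naive_diffuse(state: SimulationState, params: ModelParams) -> SimulationState:
    out = state.copy()
    D = params.D
    for _ in range(params.G):
        q = [float(v) for v in out.quorum]
        n = len(q)
        inc = [0.0] * n
        for i in range(n):
            if i > 0:
                inc[i] = inc[i] + D * (q[i - 1] - q[i])
            if i < n - 1:
                inc[i] = inc[i] + D * (q[i + 1] - q[i])
        for i in range(n):
            out.quorum[i] = q[i] + inc[i]
    return out


def naive_step(state: SimulationState, params: ModelParams) -> SimulationState:
    s = naive_evaluate(state, params)
    s = naive_divide_and_migrate(s, params)
    s = naive_produce(s, params)
    s = naive_diffuse(s, params)
    s.generation += 1
    return s
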