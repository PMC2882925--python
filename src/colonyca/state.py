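"""In-memory containers: lattice state, snapshots, and run traces.

The dish is a row of ``L`` sites.  Each site carries an integer bacterial
layer thickness, a cell state, and — while in the early-stationary state —
an age counter.  Two signal fields complete the state: a per-site quorum
concentration (substrate-borne, diffusible) and a single global odor level
(volatile, identical everywhere by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import numpy as np

from .errors import ValidationError
from .params import ModelParams

#: Sentinel stored in the age array wherever age is undefined
#: (any state other than early-stationary).
AGE_UNDEFINED = -1


class CellState(IntEnum):
    """Cell states of the automaton.

    EMPTY
        no bacteria at the site.
    S1_EXPONENTIAL
        young cells dividing exponentially; moderate quorum production.
    S2_EARLY_STATIONARY
        growth stopped (quorum above ``Qlim`` or thickness at ``N``);
        quorum production elevated ``S``-fold for ``A`` generations.
    S3_MATURE_STATIONARY
        terminally arrested; the only odor producers; absorbing.
    S4_REFRACTORY
        odor-triggered regrowth: divides, ignores quorum, produces no
        signals; arrested again at thickness ``N`` or odor ``Olim2``.
    """

    EMPTY = 0
    S1_EXPONENTIAL = 1
    S2_EARLY_STATIONARY = 2
    S3_MATURE_STATIONARY = 3
    S4_REFRACTORY = 4


#: Short display names used in trace files.
STATE_NAMES = {
    CellState.EMPTY: "EMPTY",
    CellState.S1_EXPONENTIAL: "S1",
    CellState.S2_EARLY_STATIONARY: "S2",
    CellState.S3_MATURE_STATIONARY: "S3",
    CellState.S4_REFRACTORY: "S4",
}
STATE_FROM_NAME = {v: k for k, v in STATE_NAMES.items()}

#: States in which bacteria divide this generation.
GROWING_STATES = (CellState.S1_EXPONENTIAL, CellState.S4_REFRACTORY)


@dataclass
class SimulationState:
    """Full dish snapshot at one generation.

    Arrays are plain numpy arrays of length ``L``: ``thickness`` (int64),
    ``state`` (int8, :class:`CellState` values), ``age`` (int64,
    :data:`AGE_UNDEFINED` wherever undefined) and ``quorum`` (float64).
    ``odor`` is a scalar.
    """

    generation: int
    thickness: np.ndarray
    state: np.ndarray
    age: np.ndarray
    quorum: np.ndarray
    odor: float

    @classmethod
    def empty(cls, L: int) -> "SimulationState":
        return cls(generation=0,
                   thickness=np.zeros(L, dtype=np.int64),
                   state=np.zeros(L, dtype=np.int8),
                   age=np.full(L, AGE_UNDEFINED, dtype=np.int64),
                   quorum=np.zeros(L, dtype=np.float64),
                   odor=0.0)

    @property
    def L(self) -> int:
        return len(self.state)

    def copy(self) -> "SimulationState":
        return SimulationState(self.generation,
                               self.thickness.copy(), self.state.copy(),
                               self.age.copy(), self.quorum.copy(),
                               float(self.odor))

    def occupied(self) -> np.ndarray:
        return self.state != CellState.EMPTY

    def extent(self) -> int:
        """Number of occupied sites."""
        return int(np.count_nonzero(self.state))

    def biomass(self) -> int:
        """Total thickness over the dish."""
        return int(self.thickness.sum())

    def all_mature(self) -> bool:
        """True when every occupied site is mature-stationary (the
        absorbing, growth-finished configuration)."""
        occ = self.occupied()
        return bool(occ.any()) and bool(
            (self.state[occ] == CellState.S3_MATURE_STATIONARY).all())

    def validate(self, params: Optional[ModelParams] = None) -> None:
        """Raise :class:`ValidationError` naming the offending field if any
        structural invariant is broken."""
        L = self.L
        for name in ("thickness", "age", "quorum"):
            arr = getattr(self, name)
            if len(arr) != L:
                raise ValidationError(
                    f"{name}: length {len(arr)} != lattice length {L}")
        if self.odor < 0:
            raise ValidationError(f"odor: negative ({self.odor})")
        if np.any(self.quorum < 0):
            raise ValidationError("quorum: negative concentration present")
        if not np.isfinite(self.quorum).all() or not np.isfinite(self.odor):
            raise ValidationError("quorum/odor: non-finite value present")
        if np.any(self.thickness < 0):
            raise ValidationError("thickness: negative value present")
        empty = self.state == CellState.EMPTY
        if np.any((self.thickness == 0) != empty):
            raise ValidationError(
                "thickness: zero thickness must coincide with EMPTY state")
        s2 = self.state == CellState.S2_EARLY_STATIONARY
        if np.any(self.age[s2] < 0):
            raise ValidationError("age: undefined at an early-stationary site")
        if np.any(self.age[~s2] != AGE_UNDEFINED):
            raise ValidationError("age: defined outside early-stationary state")
        if params is not None and np.any(self.thickness > params.N):
            raise ValidationError(
                f"thickness: exceeds maximum colony thickness N={params.N}")

    def __eq__(self, other: object) -> bool:  # bit-exact comparison
        if not isinstance(other, SimulationState):
            return NotImplemented
        return (self.generation == other.generation
                and self.odor == other.odor
                and np.array_equal(self.thickness, other.thickness)
                and np.array_equal(self.state, other.state)
                and np.array_equal(self.age, other.age)
                and np.array_equal(self.quorum, other.quorum))


@dataclass(frozen=True)
class Snapshot:
    """Per-generation record kept in a trace: profiles plus the odor level."""

    generation: int
    thickness: np.ndarray
    state: np.ndarray
    quorum: np.ndarray
    odor: float

    @classmethod
    def of(cls, s: SimulationState) -> "Snapshot":
        return cls(s.generation, s.thickness.copy(), s.state.copy(),
                   s.quorum.copy(), float(s.odor))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Snapshot):
            return NotImplemented
        return (self.generation == other.generation
                and self.odor == other.odor
                and np.array_equal(self.thickness, other.thickness)
                and np.array_equal(self.state, other.state)
                and np.array_equal(self.quorum, other.quorum))


@dataclass
class SimulationTrace:
    """History of one run: per-generation snapshots and summary series.

    ``snapshots[k]`` is the state after ``k`` generations (``snapshots[0]``
    is the inoculated dish).  ``terminated_at`` is the generation at which
    every occupied site had matured, or ``None`` if the generation cap was
    hit first.
    """

    params: ModelParams
    snapshots: list[Snapshot] = field(default_factory=list)
    extent_series: list[int] = field(default_factory=list)
    biomass_series: list[int] = field(default_factory=list)
    odor_series: list[float] = field(default_factory=list)
    terminated_at: Optional[int] = None

    @property
    def generations(self) -> int:
        """Number of generations executed."""
        return len(self.snapshots) - 1

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]

    @property
    def terminated(self) -> bool:
        return self.terminated_at is not None

    def snapshot_at(self, generation: int) -> Snapshot:
        for snap in self.snapshots:
            if snap.generation == generation:
                return snap
        available = [s.generation for s in self.snapshots]
        raise KeyError(
            f"generation {generation} not recorded; available: {available}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimulationTrace):
            return NotImplemented
        return (self.params == other.params
                and self.terminated_at == other.terminated_at
                and self.snapshots == other.snapshots
                and self.extent_series == other.extent_series
                and self.biomass_series == other.biomass_series
                and self.odor_series == other.odor_series)
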