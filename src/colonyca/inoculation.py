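"""Initial-lattice construction for every planting geometry simulated.

Planting geometries mirror the ways real dishes are inoculated:

``POINT``
    a single site per position — "dotting" with a needle.
``BLOCK``
    a contiguous run of ``width`` sites centered on each position —
    "dropping" a drop of suspension of a given diameter.
``RING_SECTION``
    the 1-D cross-section of a ring inoculum: two symmetric blocks of
    ``width`` sites separated by ``gap`` empty sites, centered on each
    position.
``MULTI``
    alias of POINT with several positions (kept as an explicit kind so
    configs read naturally).
``BACKGROUND``
    single-site inocula at a fixed stride across the dish — exploratory
    only.

All planted sites start in the exponential state with
``initial_thickness`` bacteria; quorum and odor start at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import ValidationError
from .params import ModelParams
from .state import CellState, SimulationState


class InoculumKind(str, Enum):
    POINT = "point"
    BLOCK = "block"
    MULTI = "multi"
    RING_SECTION = "ring_section"
    BACKGROUND = "background"


@dataclass(frozen=True)
class InoculumSpec:
    """Declarative description of a planting layout."""

    kind: InoculumKind
    positions: tuple[int, ...] = field(default=())
    width: int = 1
    gap: int = 0
    initial_thickness: int = 1
    stride: int = 10  # BACKGROUND only

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", InoculumKind(self.kind))
        object.__setattr__(self, "positions", tuple(self.positions))
        if self.width < 1:
            raise ValidationError(f"width: must be >= 1, got {self.width}")
        if self.initial_thickness < 1:
            raise ValidationError(
                f"initial_thickness: must be >= 1, got {self.initial_thickness}")
        if self.gap < 0:
            raise ValidationError(f"gap: must be >= 0, got {self.gap}")
        if self.stride < 1:
            raise ValidationError(f"stride: must be >= 1, got {self.stride}")
        if self.kind is not InoculumKind.BACKGROUND and not self.positions:
            raise ValidationError("positions: at least one position required")

    def site_runs(self, L: int) -> list[range]:
        """Occupied index ranges implied by the spec on a lattice of
        length ``L``.  Even widths take the extra site on the left."""
        runs: list[range] = []
        if self.kind is InoculumKind.BACKGROUND:
            for start in range(0, L, self.stride):
                runs.append(range(start, start + 1))
            return runs
        for center in self.positions:
            if self.kind in (InoculumKind.POINT, InoculumKind.MULTI):
                runs.append(range(center, center + 1))
            elif self.kind is InoculumKind.BLOCK:
                runs.append(_centered_run(center, self.width))
            elif self.kind is InoculumKind.RING_SECTION:
                # two blocks flanking a centered gap of exactly `gap` sites
                gap_run = _centered_run(center, self.gap)
                runs.append(range(gap_run.start - self.width, gap_run.start))
                runs.append(range(gap_run.stop, gap_run.stop + self.width))
        return runs


def _centered_run(center: int, width: int) -> range:
    """Sites of a width-`width` block centered at `center`; even widths
    occupy the extra site on the left."""
    left = center - width // 2
    return range(left, left + width)


def build_inoculum(spec: InoculumSpec, params: ModelParams) -> SimulationState:
    """Materialize a spec into a generation-0 dish state.

    Raises :class:`ValidationError` on out-of-range or overlapping
    placements, or an initial thickness above ``N``.
    """
    if spec.initial_thickness > params.N:
        raise ValidationError(
            f"initial_thickness: {spec.initial_thickness} exceeds N={params.N}")
    state = SimulationState.empty(params.L)
    seen: set[int] = set()
    for run in spec.site_runs(params.L):
        for i in run:
            if not 0 <= i < params.L:
                raise ValidationError(
                    f"positions: site {i} outside lattice [0, {params.L})")
            if i in seen:
                raise ValidationError(
                    f"positions: site {i} planted twice (overlapping elements)")
            seen.add(i)
            state.thickness[i] = spec.initial_thickness
            state.state[i] = CellState.S1_EXPONENTIAL
    return state


def point_inoculum(params: ModelParams,
                   center: int | None = None) -> SimulationState:
    """Single-site inoculum, centered on the dish by default."""
    c = params.L // 2 if center is None else center
    return build_inoculum(
        InoculumSpec(InoculumKind.POINT, positions=(c,)), params)


def pair_inoculum(params: ModelParams, separation: int,
                  center: int | None = None) -> SimulationState:
    """Two point inocula `separation` sites apart, centered on the dish."""
    if separation < 1:
        raise ValidationError(
            f"separation: must be >= 1 (same-site planting overlaps), "
            f"got {separation}")
    c = params.L // 2 if center is None else center
    left = c - (separation + 1) // 2
    right = left + separation
    return build_inoculum(
        InoculumSpec(InoculumKind.MULTI, positions=(left, right)), params)


def block_inoculum(params: ModelParams, width: int,
                   center: int | None = None) -> SimulationState:
    """Single block of `width` sites centered on the dish by default."""
    c = params.L // 2 if center is None else center
    return build_inoculum(
        InoculumSpec(InoculumKind.BLOCK, positions=(c,), width=width), params)
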