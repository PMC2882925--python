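"""Model parameters for one simulated clone.

The automaton is controlled by a small set of rates and thresholds:

``N``
    maximum colony thickness — bacteria per lattice site; stands in for
    nutrient limitation (growth stops when a site is ``N`` deep).
``P``
    quorum production factor — quorum units produced per exponentially
    growing bacterium per generation.
``S``
    stationary-to-exponential quorum production ratio — early-stationary
    bacteria produce ``S * P`` quorum units each per generation.
``A``
    quorum production window — generations a site spends in the
    early-stationary, quorum-overproducing state before maturing.
``O``
    odor production factor — odor units per mature-stationary bacterium
    per generation; odor pools globally (volatile, absorbed everywhere).
``D``
    normalized diffusion factor — fraction of the pairwise concentration
    difference exchanged per diffusion iteration; must stay in [0, 0.5]
    for the explicit scheme to be non-oscillatory.
``G``
    diffusion iterations nested inside each generation.
``Qlim``
    quorum concentration above which quorum-sensitive growth stops.
``Olim1``
    odor level that switches growing/early-stationary cells into the
    refractory growing state.
``Olim2``
    odor level that finally arrests refractory growth.

``L`` (lattice length) and ``max_generations`` are run controls, not
biology.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .errors import ConfigError

#: Values printed for the reference rimmed-colony simulations; the three
#: sensitivity thresholds are not part of this set (they are tuned, see
#: :func:`colonyca.experiments.tune_thresholds`).
REFERENCE_PARAMS = dict(N=140, P=1.0, S=10.0, A=5, O=0.01, D=0.495, G=5)

DEFAULT_MAX_GENERATIONS = 10_000


@dataclass(frozen=True)
class ModelParams:
    """All rates, thresholds and lattice/run controls for one clone."""

    N: int
    P: float
    S: float
    A: int
    O: float
    D: float
    G: int
    Qlim: float
    Olim1: float
    Olim2: float
    L: int
    max_generations: int = DEFAULT_MAX_GENERATIONS

    def __post_init__(self) -> None:
        for name in ("N", "P", "S", "A", "O", "D", "G",
                     "Qlim", "Olim1", "Olim2", "L", "max_generations"):
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"{name}: expected a number, got {value!r}")
            if value < 0:
                raise ConfigError(f"{name}: must be nonnegative, got {value!r}")
        for name in ("N", "A", "G", "L", "max_generations"):
            value = getattr(self, name)
            if int(value) != value:
                raise ConfigError(f"{name}: must be an integer, got {value!r}")
            object.__setattr__(self, name, int(value))
        if self.N < 1:
            raise ConfigError(f"N: must be >= 1, got {self.N}")
        if self.G < 1:
            raise ConfigError(f"G: must be >= 1, got {self.G}")
        if self.L < 3:
            raise ConfigError(f"L: must be >= 3, got {self.L}")
        if self.max_generations < 1:
            raise ConfigError(
                f"max_generations: must be >= 1, got {self.max_generations}")
        if not 0.0 <= self.D <= 0.5:
            raise ConfigError(
                f"D: must lie in [0, 0.5] (pairwise exchange beyond half the "
                f"difference oscillates), got {self.D}")
        if self.Olim1 > self.Olim2:
            raise ConfigError(
                f"Olim1: must be <= Olim2, got Olim1={self.Olim1} > "
                f"Olim2={self.Olim2}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def with_thresholds(self, Qlim: float, Olim1: float,
                        Olim2: float) -> "ModelParams":
        """Copy with only the three sensitivity thresholds changed."""
        return self.replace(Qlim=Qlim, Olim1=Olim1, Olim2=Olim2)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def reference_params(Qlim: float, Olim1: float, Olim2: float,
                     L: int = 301,
                     max_generations: int = DEFAULT_MAX_GENERATIONS,
                     ) -> ModelParams:
    """Reference parameter set for the rimmed-colony simulations, completed
    with caller-supplied sensitivity thresholds."""
    return ModelParams(L=L, max_generations=max_generations,
                       Qlim=Qlim, Olim1=Olim1, Olim2=Olim2,
                       **REFERENCE_PARAMS)
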