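"""Scripted scenarios: threshold tuning, rimmed-vs-rimless, colony
encounters, and the inoculum-size sweep.

The three sensitivity thresholds (``Qlim``, ``Olim1``, ``Olim2``) are the
one part of the reference parameter set that is not available as printed
numbers, so they are recovered by a grid search
(:func:`tune_thresholds`): every candidate triple is run from a
single-point inoculum and kept if the run terminates and classifies as a
rimmed colony.  The shipped defaults come from this search.

All scenarios are deterministic: re-running any of them with the same
configuration reproduces its tables bit-identically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .automaton import run_simulation
from .errors import SimulationError
from .inoculation import block_inoculum, pair_inoculum, point_inoculum
from .params import ModelParams, reference_params
from .phenotype import Phenotype, PhenotypeReport, classify_trace
from .state import SimulationTrace

#: Thresholds recovered by the default grid search (tuned, not printed):
#: the feasible triple whose singleton colony shows a well-proportioned
#: three-zone anatomy and whose inoculum-size response reproduces the
#: rimmed -> macula morphology sequence.
TUNED_RIMMED_THRESHOLDS = (1000.0, 100.0, 220.0)
#: Rimless partner: identical except for the quorum sensitivity — raising
#: Qlim beyond reach removes ring and rim while every other parameter
#: stays bit-identical.
TUNED_RIMLESS_THRESHOLDS = (20000.0, 100.0, 220.0)

#: Default tuning grids.  Qlim spans, logarithmically, the quorum scale a
#: colony of up to N-thick sites producing P (growing) to S*P (early
#: stationary) units per bacterium accumulates within tens of
#: generations; Olim1 spans the odor scale implied by O = 0.01 per mature
#: bacterium and a mature biomass of order 10^3-10^4; Olim2 is searched
#: as a multiple of Olim1 (the refractory window is what matters).
DEFAULT_QLIM_GRID = (100.0, 300.0, 1000.0, 3000.0, 10000.0, 30000.0)
DEFAULT_OLIM1_GRID = (10.0, 30.0, 100.0, 300.0)
DEFAULT_OLIM2_FACTORS = (1.2, 2.2, 5.0, 10.0)

DEFAULT_LATTICE = 351
#: Separations below ~16 sites let the two plantings fuse into a single
#: navel outright (no encounter left to observe); beyond 80 the colonies
#: barely interact.
DEFAULT_SEPARATIONS = tuple(range(16, 81, 4))
#: Odd widths keep blocks centered on a lattice site, so the whole sweep
#: stays mirror-symmetric; the range spans well past the reference
#: colony's critical (ring outer) diameter.
DEFAULT_SWEEP_WIDTHS = tuple(range(1, 42, 2))


@dataclass(frozen=True)
class TuningOutcome:
    """One grid cell of the threshold search."""

    Qlim: float
    Olim1: float
    Olim2: float
    terminated: bool
    generations: Optional[int]
    classification: Optional[Phenotype]

    @property
    def feasible(self) -> bool:
        return self.terminated and self.classification is Phenotype.RIMMED


@dataclass
class TuningResult:
    """Full grid outcome (phase table) plus the feasible triples, in grid
    order (deterministic)."""

    outcomes: list[TuningOutcome]
    feasible: list[tuple[float, float, float]]

    @property
    def selected(self) -> tuple[float, float, float]:
        return self.feasible[0]

    def phase_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"Qlim": o.Qlim, "Olim1": o.Olim1, "Olim2": o.Olim2,
              "terminated": o.terminated, "generations": o.generations,
              "classification":
                  o.classification.value if o.classification else None,
              "feasible": o.feasible}
             for o in self.outcomes])


def _run_point(params: ModelParams) -> SimulationTrace:
    return run_simulation(point_inoculum(params), params)


def tune_thresholds(params_base: Optional[ModelParams] = None,
                    qlim_grid: Sequence[float] = DEFAULT_QLIM_GRID,
                    olim1_grid: Sequence[float] = DEFAULT_OLIM1_GRID,
                    olim2_factors: Sequence[float] = DEFAULT_OLIM2_FACTORS,
                    ) -> TuningResult:
    """Grid-search the three sensitivity thresholds.

    A triple is feasible when a single-point inoculum run under
    ``params_base`` (the reference rates by default) terminates and its
    final profile classifies as RIMMED.  Raises
    :class:`SimulationError` when the grid contains no feasible triple.
    """
    if params_base is None:
        params_base = reference_params(1.0, 1.0, 1.0, L=DEFAULT_LATTICE,
                                       max_generations=2000)
    outcomes: list[TuningOutcome] = []
    feasible: list[tuple[float, float, float]] = []
    for Qlim, Olim1, factor in itertools.product(qlim_grid, olim1_grid,
                                                 olim2_factors):
        Olim2 = round(Olim1 * factor, 9)  # keep grid values clean decimals
        if Olim1 > Olim2:
            continue
        params = params_base.with_thresholds(Qlim, Olim1, Olim2)
        trace = _run_point(params)
        if trace.terminated:
            label = classify_trace(trace).classification
            outcome = TuningOutcome(Qlim, Olim1, Olim2, True,
                                    trace.terminated_at, label)
        else:
            outcome = TuningOutcome(Qlim, Olim1, Olim2, False, None, None)
        outcomes.append(outcome)
        if outcome.feasible:
            feasible.append((Qlim, Olim1, Olim2))
    if not feasible:
        raise SimulationError(
            "threshold tuning: no feasible (Qlim, Olim1, Olim2) triple in "
            "the grid produced a terminated rimmed colony; widen the grid")
    return TuningResult(outcomes, feasible)


@dataclass(frozen=True)
class PairedPhenotypes:
    """Outcome of the rimmed-vs-rimless comparison."""

    rimmed_params: ModelParams
    rimless_params: ModelParams
    rimmed_trace: SimulationTrace
    rimless_trace: SimulationTrace
    rimmed_report: PhenotypeReport
    rimless_report: PhenotypeReport


def scenario_rimmed_vs_rimless(
        rimmed_thresholds: tuple[float, float, float] = TUNED_RIMMED_THRESHOLDS,
        rimless_thresholds: tuple[float, float, float] = TUNED_RIMLESS_THRESHOLDS,
        params_base: Optional[ModelParams] = None) -> PairedPhenotypes:
    """Run the same clone under two threshold triples and classify both.

    Every non-threshold parameter is bit-identical between the two runs;
    the phenotype difference is carried entirely by the sensitivity
    limits.  With the shipped defaults the first run is RIMMED and the
    second RIMLESS.
    """
    if params_base is None:
        params_base = reference_params(1.0, 1.0, 1.0, L=DEFAULT_LATTICE,
                                       max_generations=2000)
    p_rimmed = params_base.with_thresholds(*rimmed_thresholds)
    p_rimless = params_base.with_thresholds(*rimless_thresholds)
    t_rimmed = _run_point(p_rimmed)
    t_rimless = _run_point(p_rimless)
    return PairedPhenotypes(p_rimmed, p_rimless, t_rimmed, t_rimless,
                            classify_trace(t_rimmed),
                            classify_trace(t_rimless))


@dataclass
class EncounterResult:
    """Per-separation outcomes for paired point inocula, plus the
    singleton control under identical parameters."""

    params: ModelParams
    singleton_report: PhenotypeReport
    table: pd.DataFrame = field(repr=False)
    crossover_separation: Optional[int] = None

    @property
    def singleton_diameter(self) -> int:
        return max(c.total_diameter for c in self.singleton_report.colonies)

    @property
    def singleton_maturity(self) -> int:
        return self.singleton_report.generations_to_maturity


def scenario_encounters(
        separations: Sequence[int] = DEFAULT_SEPARATIONS,
        thresholds: tuple[float, float, float] = TUNED_RIMMED_THRESHOLDS,
        params_base: Optional[ModelParams] = None) -> EncounterResult:
    """Plant two point inocula at each separation and compare with a
    singleton grown under identical parameters.

    Reports, per separation: classification, colony count, per-colony
    diameters, and generations to maturity.  The crossover separation is
    the largest scanned separation whose pair still fuses under a common
    rim (classifies CONFLUENT_RIMMED); at larger separations the pair
    resolves into two independent rimmed colonies.
    """
    if params_base is None:
        params_base = reference_params(1.0, 1.0, 1.0, L=DEFAULT_LATTICE,
                                       max_generations=2000)
    params = params_base.with_thresholds(*thresholds)
    singleton = classify_trace(_run_point(params))

    rows = []
    crossover: Optional[int] = None
    for sep in separations:
        trace = run_simulation(pair_inoculum(params, sep), params)
        report = classify_trace(trace)
        diameters = [c.total_diameter for c in report.colonies]
        rows.append({
            "separation": sep,
            "classification": report.classification.value,
            "colony_count": report.colony_count,
            "max_colony_diameter": max(diameters),
            "colony_diameters": ",".join(map(str, diameters)),
            "generations_to_maturity": report.generations_to_maturity,
        })
        if report.classification is Phenotype.CONFLUENT_RIMMED:
            crossover = sep
    return EncounterResult(params, singleton, pd.DataFrame(rows), crossover)


@dataclass
class SweepResult:
    """Inoculum-size sweep: per-width morphometrics and classification."""

    params: ModelParams
    macula_reference_width: int
    table: pd.DataFrame = field(repr=False)

    @property
    def first_macula_width(self) -> Optional[int]:
        hits = self.table[self.table.classification == Phenotype.MACULA.value]
        return None if hits.empty else int(hits.width.iloc[0])


def scenario_inoculum_sweep(
        widths: Sequence[int] = DEFAULT_SWEEP_WIDTHS,
        thresholds: tuple[float, float, float] = TUNED_RIMMED_THRESHOLDS,
        params_base: Optional[ModelParams] = None) -> SweepResult:
    """Run BLOCK inocula of increasing width ("dropping" ever larger
    drops) and tabulate the morphology response.

    The singleton (width-1) colony provides the macula reference: its
    ring outer diameter (navel plus interstitial ring) is the critical
    planting width beyond which no room remains for the ring.  With the
    shipped thresholds the table shows the navel widening and the ring
    narrowing as inocula grow, with classification passing from RIMMED to
    MACULA and never reverting.
    """
    if params_base is None:
        params_base = reference_params(1.0, 1.0, 1.0, L=DEFAULT_LATTICE,
                                       max_generations=2000)
    params = params_base.with_thresholds(*thresholds)
    singleton = classify_trace(_run_point(params))
    reference = max(singleton.colonies,
                    key=lambda c: c.total_diameter).ring_outer_diameter

    rows = []
    for width in widths:
        trace = run_simulation(block_inoculum(params, width), params)
        report = classify_trace(trace, macula_reference_width=reference)
        colony = max(report.colonies, key=lambda c: c.total_diameter)
        rows.append({
            "width": width,
            "classification": report.classification.value,
            "navel_diameter": colony.navel_diameter,
            "ring_diameter": colony.ring_diameter,
            "rim_diameter": colony.rim_diameter,
            "total_diameter": colony.total_diameter,
            "imperfect_rim": colony.imperfect_rim,
            "generations_to_maturity": report.generations_to_maturity,
        })
    return SweepResult(params, reference, pd.DataFrame(rows))
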