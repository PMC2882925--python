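"""Zone segmentation and phenotype classification of thickness profiles.

A mature rimmed colony's cross-section shows three zones: a thick central
*navel*, a flat thin *interstitial* ring, and a thick peripheral *rim*.
Rimless colonies lack ring and rim; over-wide inocula collapse into
undifferentiated *maculae*; closely planted colonies can fuse under a
common rim (*confluent*).

Segmentation is deliberately simple: occupied sites are split into TALL
(thickness >= ``tall_fraction * N``, default half-maximal) and THIN runs,
and run patterns are mapped onto zone labels.  The thickness cut is the
one genuinely free choice here — profiles are strongly bimodal, so any
mid-range fraction separates navel/rim from the interstitial ring — and
it is exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .errors import PartialTraceError, ValidationError
from .params import ModelParams
from .state import SimulationTrace

DEFAULT_TALL_FRACTION = 0.5
#: Colonies narrower than this never developed recognizable structure.
DEFAULT_MIN_EXTENT = 5
#: A rim thinner than this fraction of the navel is reported as imperfect.
IMPERFECT_RIM_RATIO = 0.8


class ZoneLabel(str, Enum):
    NAVEL = "navel"
    INTERSTITIAL = "interstitial"
    RIM = "rim"


class Phenotype(str, Enum):
    RIMMED = "rimmed"
    RIMLESS = "rimless"
    MACULA = "macula"
    CONFLUENT_RIMMED = "confluent_rimmed"
    UNDEVELOPED = "undeveloped"


@dataclass(frozen=True)
class Zone:
    """Half-open site interval [start, stop) with a label."""

    label: ZoneLabel
    start: int
    stop: int
    mean_thickness: float

    @property
    def width(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class ColonySegmentation:
    """Zones of one connected colony (maximal run of occupied sites)."""

    start: int
    stop: int
    zones: tuple[Zone, ...]

    @property
    def width(self) -> int:
        return self.stop - self.start

    def zone_width(self, label: ZoneLabel) -> int:
        return sum(z.width for z in self.zones if z.label is label)

    def count(self, label: ZoneLabel) -> int:
        return sum(1 for z in self.zones if z.label is label)


@dataclass(frozen=True)
class ZoneSegmentation:
    """Per-colony zone lists for one thickness profile."""

    colonies: tuple[ColonySegmentation, ...]
    tall_threshold: float
    tall_fraction: float


@dataclass(frozen=True)
class ColonyReport:
    """Morphometrics of one colony.

    ``interstitial_diameter`` counts every thin zone of the colony, so the
    navel/interstitial/rim diameters sum to the total.  ``ring_diameter``
    counts only the interstitial ring proper — thin sites lying between
    the outermost thick zones — excluding the thin outer skirt left
    beyond the rim when growth arrests; ``ring_outer_diameter`` is the
    navel plus that ring (the span out to the rim's inner edge), the
    critical planting diameter beyond which no room remains for the ring.
    """

    start: int
    stop: int
    total_diameter: int
    navel_diameter: int
    interstitial_diameter: int
    rim_diameter: int
    ring_diameter: int
    classification: Phenotype
    rim_to_navel_ratio: Optional[float]
    imperfect_rim: bool

    @property
    def ring_outer_diameter(self) -> int:
        return self.navel_diameter + self.ring_diameter


@dataclass(frozen=True)
class PhenotypeReport:
    classification: Phenotype
    colony_count: int
    colonies: tuple[ColonyReport, ...]
    total_diameter: int
    generations_to_maturity: Optional[int]

    def to_dict(self) -> dict:
        return {
            "classification": self.classification.value,
            "colony_count": self.colony_count,
            "total_diameter": self.total_diameter,
            "generations_to_maturity": self.generations_to_maturity,
            "colonies": [
                {
                    "start": c.start,
                    "stop": c.stop,
                    "total_diameter": c.total_diameter,
                    "navel_diameter": c.navel_diameter,
                    "interstitial_diameter": c.interstitial_diameter,
                    "rim_diameter": c.rim_diameter,
                    "ring_diameter": c.ring_diameter,
                    "ring_outer_diameter": c.ring_outer_diameter,
                    "classification": c.classification.value,
                    "rim_to_navel_ratio": c.rim_to_navel_ratio,
                    "imperfect_rim": c.imperfect_rim,
                }
                for c in self.colonies
            ],
        }


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean array."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def segment_zones(profile: Sequence[float] | np.ndarray,
                  params: ModelParams,
                  tall_fraction: float = DEFAULT_TALL_FRACTION,
                  ) -> ZoneSegmentation:
    """Segment a thickness profile into labeled zones, colony by colony.

    Within one colony, runs of TALL/THIN sites are labeled as follows:
    a single TALL run is the navel; with exactly two TALL runs the inner
    (first) one is the navel and the outer one the rim; with three or
    more, the outermost two are rims and every inner TALL run a navel.
    THIN runs are interstitial.  Zones are reported left to right.

    Raises :class:`ValidationError` for an all-empty profile.
    """
    if not 0.0 < tall_fraction < 1.0:
        raise ValidationError(
            f"tall_fraction: must lie in (0, 1), got {tall_fraction}")
    prof = np.asarray(profile, dtype=np.float64)
    occupied = prof > 0
    if not occupied.any():
        raise ValidationError("no colony: profile is entirely empty")
    threshold = tall_fraction * params.N

    colonies: list[ColonySegmentation] = []
    for cstart, cstop in _runs(occupied):
        local = prof[cstart:cstop]
        tall = local >= threshold
        run_list: list[tuple[int, int, bool]] = []  # start, stop, is_tall
        i = 0
        while i < len(local):
            j = i
            while j < len(local) and tall[j] == tall[i]:
                j += 1
            run_list.append((i, j, bool(tall[i])))
            i = j
        tall_indices = [k for k, r in enumerate(run_list) if r[2]]
        labels: dict[int, ZoneLabel] = {}
        if len(tall_indices) == 1:
            labels[tall_indices[0]] = ZoneLabel.NAVEL
        elif len(tall_indices) == 2:
            labels[tall_indices[0]] = ZoneLabel.NAVEL
            labels[tall_indices[1]] = ZoneLabel.RIM
        elif len(tall_indices) >= 3:
            labels[tall_indices[0]] = ZoneLabel.RIM
            labels[tall_indices[-1]] = ZoneLabel.RIM
            for k in tall_indices[1:-1]:
                labels[k] = ZoneLabel.NAVEL
        zones = tuple(
            Zone(label=labels.get(k, ZoneLabel.INTERSTITIAL),
                 start=cstart + rs, stop=cstart + re,
                 mean_thickness=float(local[rs:re].mean()))
            for k, (rs, re, _) in enumerate(run_list))
        colonies.append(ColonySegmentation(cstart, cstop, zones))
    return ZoneSegmentation(tuple(colonies), threshold, tall_fraction)


def _flanks_decay_monotonically(profile: np.ndarray,
                                colony: ColonySegmentation) -> bool:
    """True when thickness decays (non-strictly) outward from the single
    tall zone to both colony edges — the rimless shape, with plateaus
    allowed and no peripheral rebound."""
    tall = [z for z in colony.zones if z.label is ZoneLabel.NAVEL]
    if len(tall) != 1:
        return False
    z = tall[0]
    left = profile[colony.start:z.start + 1]
    right = profile[z.stop - 1:colony.stop]
    return bool(np.all(np.diff(left) >= 0) and np.all(np.diff(right) <= 0))


def _ring_width(colony: ColonySegmentation) -> int:
    """Width of the interstitial ring proper: thin zones strictly between
    the outermost thick (navel/rim) zones."""
    thick = [k for k, z in enumerate(colony.zones)
             if z.label is not ZoneLabel.INTERSTITIAL]
    if not thick:
        return 0
    return sum(z.width for z in colony.zones[thick[0]:thick[-1] + 1]
               if z.label is ZoneLabel.INTERSTITIAL)


def _classify_colony(profile: np.ndarray, colony: ColonySegmentation,
                     macula_reference_width: Optional[float],
                     min_extent: int) -> ColonyReport:
    navel_w = colony.zone_width(ZoneLabel.NAVEL)
    inter_w = colony.zone_width(ZoneLabel.INTERSTITIAL)
    rim_w = colony.zone_width(ZoneLabel.RIM)
    n_navel = colony.count(ZoneLabel.NAVEL)
    n_rim = colony.count(ZoneLabel.RIM)

    navel_zones = [z for z in colony.zones if z.label is ZoneLabel.NAVEL]
    rim_zones = [z for z in colony.zones if z.label is ZoneLabel.RIM]
    ratio = None
    if navel_zones and rim_zones:
        navel_peak = max(z.mean_thickness for z in navel_zones)
        rim_peak = max(z.mean_thickness for z in rim_zones)
        ratio = rim_peak / navel_peak if navel_peak > 0 else None
    imperfect = ratio is not None and ratio < IMPERFECT_RIM_RATIO

    if colony.width < min_extent:
        label = Phenotype.UNDEVELOPED
    elif n_navel >= 2 and n_rim >= 2:
        label = Phenotype.CONFLUENT_RIMMED
    elif n_navel >= 1 and n_rim >= 1 and inter_w >= 1:
        label = Phenotype.RIMMED
    elif n_navel == 1 and n_rim == 0:
        if (macula_reference_width is not None
                and navel_w >= macula_reference_width):
            label = Phenotype.MACULA
        elif _flanks_decay_monotonically(profile, colony):
            label = Phenotype.RIMLESS
        else:
            label = Phenotype.MACULA
    else:
        label = Phenotype.UNDEVELOPED
    return ColonyReport(colony.start, colony.stop, colony.width,
                        navel_w, inter_w, rim_w, _ring_width(colony),
                        label, ratio, imperfect)


def classify(segmentation: ZoneSegmentation,
             trace: SimulationTrace,
             macula_reference_width: Optional[float] = None,
             min_extent: int = DEFAULT_MIN_EXTENT,
             ) -> PhenotypeReport:
    """Classify a segmented final profile into a phenotype.

    Rules, per colony: navel + interstitial + rim is RIMMED; two or more
    navels sharing one outermost rim pair is CONFLUENT_RIMMED; a single
    tall zone with monotonically decaying flanks and no rim is RIMLESS; a
    single tall zone at least as wide as ``macula_reference_width`` (the
    interstitial outer diameter of a reference rimmed colony, when
    supplied) is MACULA, as is any rimless-shaped body failing the
    monotone-decay test; anything narrower than ``min_extent`` sites is
    UNDEVELOPED.  The overall label is the confluent one if any colony
    fused, otherwise the label of the widest colony.

    Classification is refused (:class:`PartialTraceError`) for traces
    that hit the generation cap: their profile is still developing.
    """
    if not trace.terminated:
        raise PartialTraceError(
            "trace did not terminate (generation cap reached); "
            "classification of a partial profile is refused")
    profile = np.asarray(trace.final.thickness, dtype=np.float64)
    reports = tuple(
        _classify_colony(profile, colony, macula_reference_width, min_extent)
        for colony in segmentation.colonies)
    if any(r.classification is Phenotype.CONFLUENT_RIMMED for r in reports):
        overall = Phenotype.CONFLUENT_RIMMED
    else:
        widest = max(reports, key=lambda r: r.total_diameter)
        overall = widest.classification
    return PhenotypeReport(
        classification=overall,
        colony_count=len(reports),
        colonies=reports,
        total_diameter=sum(r.total_diameter for r in reports),
        generations_to_maturity=trace.terminated_at,
    )


def classify_trace(trace: SimulationTrace,
                   tall_fraction: float = DEFAULT_TALL_FRACTION,
                   macula_reference_width: Optional[float] = None,
                   min_extent: int = DEFAULT_MIN_EXTENT) -> PhenotypeReport:
    """Convenience: segment the final profile of a trace and classify it."""
    seg = segment_zones(trace.final.thickness, trace.params, tall_fraction)
    return classify(seg, trace, macula_reference_width, min_extent)


def synthetic_profile(zone_recipe: Sequence[tuple[int, float]],
                      L: int, offset: int = 0) -> np.ndarray:
    """Build a synthetic thickness profile from a zone recipe.

    ``zone_recipe`` is a list of (width, level) pairs laid out left to
    right starting at ``offset``; the rest of the lattice is empty.  Used
    to exercise the classifier without running a simulation.
    """
    profile = np.zeros(L, dtype=np.float64)
    pos = offset
    for width, level in zone_recipe:
        if pos + width > L:
            raise ValidationError(
                f"zone recipe overruns lattice: needs {pos + width} > L={L}")
        profile[pos:pos + width] = level
        pos += width
    return profile
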