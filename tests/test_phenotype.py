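"""Classifier tests on synthetic profiles with known zone structure, plus
invariance properties."""

import numpy as np
import pytest

from colonyca.errors import PartialTraceError, ValidationError
from colonyca.params import ModelParams
from colonyca.phenotype import (Phenotype, ZoneLabel, classify,
                                classify_trace, segment_zones,
                                synthetic_profile)
from colonyca.state import SimulationTrace, Snapshot

N = 140


@pytest.fixture
def params():
    return ModelParams(N=N, P=1.0, S=10.0, A=5, O=0.01, D=0.495, G=5,
                       Qlim=1000.0, Olim1=100.0, Olim2=220.0, L=120)


def fake_trace(profile, params, terminated_at=30):
    """Wrap a profile in a minimal terminated trace for classify()."""
    profile = np.asarray(profile)
    state = np.where(profile > 0, 3, 0).astype(np.int8)
    snap = Snapshot(terminated_at or 0, profile.astype(np.int64), state,
                    np.zeros_like(profile, dtype=float), 1.0)
    return SimulationTrace(params=params, snapshots=[snap],
                           extent_series=[int((profile > 0).sum())],
                           biomass_series=[int(profile.sum())],
                           odor_series=[1.0], terminated_at=terminated_at)


class TestSegmentation:
    def test_single_tall_run_is_navel(self, params):
        profile = synthetic_profile([(3, N)], params.L, offset=40)
        seg = segment_zones(profile, params)
        (colony,) = seg.colonies
        assert [z.label for z in colony.zones] == [ZoneLabel.NAVEL]
        assert colony.zones[0].width == 3

    def test_tall_thin_tall_maps_navel_interstitial_rim(self, params):
        profile = synthetic_profile([(5, N), (8, 20), (3, N)], params.L,
                                    offset=40)
        seg = segment_zones(profile, params)
        (colony,) = seg.colonies
        assert [(z.label, z.width) for z in colony.zones] == [
            (ZoneLabel.NAVEL, 5), (ZoneLabel.INTERSTITIAL, 8),
            (ZoneLabel.RIM, 3)]

    def test_full_symmetric_anatomy(self, params):
        profile = synthetic_profile(
            [(4, N), (6, 20), (5, N), (6, 20), (4, N)], params.L, offset=40)
        seg = segment_zones(profile, params)
        labels = [z.label for z in seg.colonies[0].zones]
        assert labels == [ZoneLabel.RIM, ZoneLabel.INTERSTITIAL,
                          ZoneLabel.NAVEL, ZoneLabel.INTERSTITIAL,
                          ZoneLabel.RIM]

    def test_recovers_generating_boundaries_exactly(self, params):
        recipe = [(7, 130), (11, 30), (4, 120)]
        profile = synthetic_profile(recipe, params.L, offset=25)
        seg = segment_zones(profile, params)
        (colony,) = seg.colonies
        starts = [z.start for z in colony.zones]
        widths = [z.width for z in colony.zones]
        assert starts == [25, 32, 43]
        assert widths == [7, 11, 4]
        assert [z.mean_thickness for z in colony.zones] == [130, 30, 120]

    def test_two_separated_colonies_segment_independently(self, params):
        profile = (synthetic_profile([(3, N)], params.L, offset=10)
                   + synthetic_profile([(4, N)], params.L, offset=50))
        seg = segment_zones(profile, params)
        assert len(seg.colonies) == 2
        assert seg.colonies[0].width == 3 and seg.colonies[1].width == 4

    def test_single_empty_site_separates_colonies(self, params):
        profile = np.zeros(params.L)
        profile[10:15] = N
        profile[16:20] = N  # one empty site at 15
        seg = segment_zones(profile, params)
        assert len(seg.colonies) == 2

    def test_empty_profile_rejected(self, params):
        with pytest.raises(ValidationError, match="no colony"):
            segment_zones(np.zeros(params.L), params)

    def test_tall_fraction_bounds(self, params):
        with pytest.raises(ValidationError, match="tall_fraction"):
            segment_zones(np.ones(params.L), params, tall_fraction=1.0)


class TestClassification:
    def test_three_zone_anatomy_is_rimmed(self, params):
        profile = synthetic_profile(
            [(4, N), (6, 20), (5, N), (6, 20), (4, N)], params.L, offset=40)
        report = classify(segment_zones(profile, params),
                          fake_trace(profile, params))
        assert report.classification is Phenotype.RIMMED
        assert report.generations_to_maturity == 30

    def test_two_navels_in_one_rim_pair_is_confluent(self, params):
        profile = synthetic_profile(
            [(4, N), (5, 20), (4, N), (6, 20), (4, N), (5, 20), (4, N)],
            params.L, offset=30)
        report = classify(segment_zones(profile, params),
                          fake_trace(profile, params))
        assert report.classification is Phenotype.CONFLUENT_RIMMED

    def test_monotone_decay_without_rim_is_rimless(self, params):
        profile = synthetic_profile(
            [(1, 4), (1, 16), (1, 64), (5, N), (1, 64), (1, 16), (1, 4)],
            params.L, offset=40)
        report = classify(segment_zones(profile, params),
                          fake_trace(profile, params))
        assert report.classification is Phenotype.RIMLESS

    def test_wide_plateau_beyond_reference_is_macula(self, params):
        profile = synthetic_profile([(30, N), (4, 10)], params.L, offset=40)
        report = classify(segment_zones(profile, params),
                          fake_trace(profile, params),
                          macula_reference_width=21)
        assert report.classification is Phenotype.MACULA

    def test_tiny_colony_is_undeveloped(self, params):
        profile = synthetic_profile([(2, N)], params.L, offset=40)
        report = classify(segment_zones(profile, params),
                          fake_trace(profile, params))
        assert report.classification is Phenotype.UNDEVELOPED

    def test_diameters_sum_to_total_per_colony(self, params):
        profile = synthetic_profile(
            [(3, 20), (4, N), (6, 20), (5, N), (6, 20), (4, N), (3, 20)],
            params.L, offset=30)
        report = classify(segment_zones(profile, params),
                          fake_trace(profile, params))
        (colony,) = report.colonies
        assert (colony.navel_diameter + colony.interstitial_diameter
                + colony.rim_diameter) == colony.total_diameter
        # the ring proper excludes the two outer skirts
        assert colony.ring_diameter == colony.interstitial_diameter - 6
        assert colony.ring_outer_diameter == 5 + 12

    def test_partial_trace_refused(self, params):
        profile = synthetic_profile([(5, N)], params.L, offset=40)
        with pytest.raises(PartialTraceError):
            classify(segment_zones(profile, params),
                     fake_trace(profile, params, terminated_at=None))

    def test_classification_invariant_under_reflection_and_shift(self, params):
        recipes = [
            [(4, N), (6, 20), (5, N), (6, 20), (4, N)],
            [(1, 16), (1, 64), (5, N), (1, 64), (1, 16)],
            [(30, N)],
        ]
        for recipe in recipes:
            profile = synthetic_profile(recipe, params.L, offset=30)
            base = classify(segment_zones(profile, params),
                            fake_trace(profile, params)).classification
            for variant in (profile[::-1].copy(), np.roll(profile, 9)):
                got = classify(segment_zones(variant, params),
                               fake_trace(variant, params)).classification
                assert got is base


def test_classify_trace_uses_terminated_generation(params):
    profile = synthetic_profile([(4, N), (6, 20), (5, N), (6, 20), (4, N)],
                                params.L, offset=40)
    trace = fake_trace(profile, params, terminated_at=42)
    report = classify_trace(trace)
    assert report.generations_to_maturity == trace.terminated_at == 42
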