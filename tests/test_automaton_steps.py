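"""Unit tests of the four generation steps against hand-worked examples
and the naive loop transcription."""

import numpy as np
import pytest

from colonyca.automaton import (diffuse_quorum, divide_and_migrate,
                                evaluate_states, produce_signals,
                                step_generation)
from colonyca.errors import ConfigError, ValidationError
from colonyca.params import ModelParams
from colonyca.state import AGE_UNDEFINED, CellState, SimulationState

from .conftest import make_state
from .reference import naive_step

S1 = CellState.S1_EXPONENTIAL
S2 = CellState.S2_EARLY_STATIONARY
S3 = CellState.S3_MATURE_STATIONARY
S4 = CellState.S4_REFRACTORY


class TestEvaluateStates:
    def test_no_trigger_leaves_growing_site_unchanged(self, small_params):
        s = make_state(small_params, {10: (S1, 5)})
        out = evaluate_states(s, small_params)
        assert out.state[10] == S1
        np.testing.assert_array_equal(out.thickness, s.thickness)

    def test_age_reaching_window_matures(self, small_params):
        s = make_state(small_params, {10: (S2, 5, small_params.A)})
        out = evaluate_states(s, small_params)
        assert out.state[10] == S3
        assert out.age[10] == AGE_UNDEFINED

    def test_age_below_window_increments(self, small_params):
        s = make_state(small_params, {10: (S2, 5, 1)})
        out = evaluate_states(s, small_params)
        assert out.state[10] == S2
        assert out.age[10] == 2

    def test_odor_takes_precedence_over_quorum(self, small_params):
        """A site whose quorum and odor triggers co-occur turns refractory,
        so it resumes growth instead of stalling."""
        quorum = np.zeros(small_params.L)
        quorum[10] = small_params.Qlim
        s = make_state(small_params, {10: (S1, 5)}, quorum=quorum,
                       odor=small_params.Olim1)
        out = evaluate_states(s, small_params)
        assert out.state[10] == S4

    def test_quorum_arrest_sets_age_zero(self, small_params):
        quorum = np.zeros(small_params.L)
        quorum[10] = small_params.Qlim
        s = make_state(small_params, {10: (S1, 5)}, quorum=quorum)
        out = evaluate_states(s, small_params)
        assert out.state[10] == S2
        assert out.age[10] == 0

    def test_thickness_cap_arrests_growth(self, small_params):
        s = make_state(small_params, {10: (S1, small_params.N)})
        out = evaluate_states(s, small_params)
        assert out.state[10] == S2

    def test_mature_state_is_absorbing(self, small_params):
        s = make_state(small_params, {10: (S3, 7)},
                       odor=10 * small_params.Olim2)
        s.quorum[:] = 10 * small_params.Qlim
        out = evaluate_states(s, small_params)
        assert out.state[10] == S3

    def test_refractory_arrest_by_odor_or_cap(self, small_params):
        s = make_state(small_params, {5: (S4, 5), 6: (S4, small_params.N)},
                       odor=0.0)
        out = evaluate_states(s, small_params)
        assert out.state[5] == S4          # no trigger
        assert out.state[6] == S3          # at thickness cap
        s2 = make_state(small_params, {5: (S4, 5)}, odor=small_params.Olim2)
        assert evaluate_states(s2, small_params).state[5] == S3

    def test_malformed_state_names_field(self, small_params):
        s = make_state(small_params, {10: (S1, 5)})
        s.quorum[3] = -1.0
        with pytest.raises(ValidationError, match="quorum"):
            evaluate_states(s, small_params)
        s = make_state(small_params, {10: (S1, 5)})
        s.quorum = s.quorum[:-1]
        with pytest.raises(ValidationError, match="quorum"):
            evaluate_states(s, small_params)


class TestDivideAndMigrate:
    def test_doubling_and_two_sided_export(self, small_params):
        # 4 doubles to 8, one daughter leaves to each flank
        s = make_state(small_params, {10: (S1, 4)})
        out = divide_and_migrate(s, small_params)
        assert out.thickness[9:12].tolist() == [1, 6, 1]
        assert out.state[9] == S1 and out.state[11] == S1

    def test_thickness_capped_at_N(self, small_params):
        s = make_state(small_params, {0: (S1, small_params.N)})
        out = divide_and_migrate(s, small_params)
        assert out.thickness[0] == small_params.N - 1  # one export right

    def test_non_growing_states_static(self, small_params):
        s = make_state(small_params, {10: (S2, 4, 0), 14: (S3, 4)})
        out = divide_and_migrate(s, small_params)
        np.testing.assert_array_equal(out.thickness, s.thickness)
        np.testing.assert_array_equal(out.state, s.state)

    def test_quorum_blocks_quorum_sensitive_colonization(self, small_params):
        quorum = np.full(small_params.L, small_params.Qlim)
        s = make_state(small_params, {10: (S1, 4)}, quorum=quorum)
        out = divide_and_migrate(s, small_params)
        assert out.state[9] == CellState.EMPTY
        assert out.state[11] == CellState.EMPTY
        assert out.thickness[10] == 8  # doubled, nothing exported

    def test_refractory_colonizer_ignores_quorum_until_final_odor(
            self, small_params):
        quorum = np.full(small_params.L, 10 * small_params.Qlim)
        s = make_state(small_params, {10: (S4, 4)}, quorum=quorum)
        out = divide_and_migrate(s, small_params)
        assert out.state[9] == S4 and out.state[11] == S4
        blocked = make_state(small_params, {10: (S4, 4)}, quorum=quorum,
                             odor=small_params.Olim2)
        out2 = divide_and_migrate(blocked, small_params)
        assert out2.state[9] == CellState.EMPTY

    def test_two_sided_tie_charges_neither_donor(self, small_params):
        # both neighbors of site 10 are eligible: the tied site gains one
        # bacterium (state from the left) and neither donor pays for it;
        # each donor still pays for its sole outward colonization
        s = make_state(small_params, {9: (S1, 4), 11: (S1, 4)})
        out = divide_and_migrate(s, small_params)
        assert out.state[10] == S1
        assert out.thickness[10] == 1
        assert out.thickness[9] == 7    # 8 minus the export to site 8
        assert out.thickness[11] == 7   # 8 minus the export to site 12
        assert out.thickness[8] == out.thickness[12] == 1

    def test_donor_floor_is_one(self, small_params):
        p = small_params.replace(N=1)
        s = make_state(p, {10: (S1, 1)})
        out = divide_and_migrate(s, p)
        # doubling capped at N=1; two exports would drive it negative
        assert out.thickness[10] == 1
        assert out.thickness[9] == out.thickness[11] == 1


class TestProduceSignals:
    def test_empty_dish_produces_nothing(self, small_params):
        s = SimulationState.empty(small_params.L)
        out = produce_signals(s, small_params)
        assert out.odor == 0.0 and out.quorum.sum() == 0.0

    def test_stationary_rate_is_S_fold(self, small_params):
        p = small_params.replace(P=1.0, S=10.0)
        s = make_state(p, {4: (S2, 10, 0)})
        out = produce_signals(s, p)
        assert out.quorum[4] == 100.0  # S * P * thickness

    def test_odor_sums_over_mature_sites(self):
        p = ModelParams(N=140, P=1.0, S=10.0, A=5, O=0.01, D=0.495, G=5,
                        Qlim=1e3, Olim1=1e2, Olim2=2e2, L=7)
        s = make_state(p, {1: (S3, 140), 2: (S3, 140), 3: (S3, 140)})
        out = produce_signals(s, p)
        assert out.odor == pytest.approx(4.2)  # 0.01 * 420
        assert out.quorum.sum() == 0.0

    def test_refractory_sites_produce_nothing(self, small_params):
        s = make_state(small_params, {4: (S4, 10)})
        out = produce_signals(s, small_params)
        assert out.odor == 0.0 and out.quorum.sum() == 0.0


class TestDiffuseQuorum:
    def test_two_site_hand_computed_flux(self):
        p = ModelParams(N=1, P=0, S=0, A=1, O=0, D=0.495, G=1,
                        Qlim=1, Olim1=0, Olim2=0, L=3)
        q = diffuse_quorum(np.array([1.0, 0.0]), p)
        np.testing.assert_allclose(q, [0.505, 0.495], rtol=0, atol=0)

    def test_uniform_field_is_fixed_point(self, small_params):
        q = np.full(small_params.L, 3.7)
        out = diffuse_quorum(q, small_params)
        np.testing.assert_array_equal(out, q)

    def test_mass_conserved(self, small_params):
        rng = np.random.default_rng(7)
        q = rng.uniform(0, 100, small_params.L)
        out = diffuse_quorum(q, small_params)
        assert out.sum() == pytest.approx(q.sum(), rel=1e-12)

    def test_unstable_factor_rejected(self, small_params):
        bad = ModelParams.__new__(ModelParams)  # bypass ctor validation
        object.__setattr__(bad, "D", 0.9)
        object.__setattr__(bad, "G", 1)
        with pytest.raises(ConfigError, match="D"):
            diffuse_quorum(np.ones(5), bad)


class TestStepGeneration:
    def test_empty_dish_is_fixed_point(self, small_params):
        s = SimulationState.empty(small_params.L)
        out = step_generation(s, small_params)
        assert out.generation == 1
        assert out.extent() == 0 and out.odor == 0.0

    def test_flank_growth_two_sites_per_generation(self, small_params):
        p = small_params.replace(Qlim=1e9, Olim1=1e9, Olim2=1e9)
        s = make_state(p, {10: (S1, 1)})
        for k in range(1, 6):
            s = step_generation(s, p)
            assert s.extent() == 1 + 2 * k

    def test_odor_strictly_increases_with_mature_site(self, small_params):
        s = make_state(small_params, {10: (S3, 7)})
        out = step_generation(s, small_params)
        assert out.odor > s.odor

    def test_matches_naive_transcription_on_small_states(self, small_params):
        from .conftest import random_state
        rng = np.random.default_rng(42)
        for _ in range(50):
            s = random_state(rng, small_params)
            fast = step_generation(s, small_params)
            slow = naive_step(s, small_params)
            assert fast == slow
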