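"""State division, assignment, transition estimation and adjustment."""

import itertools

import numpy as np
import pytest

import greymarkov as gm
from greymarkov.markov import (
    StatePath,
    StateSpace,
    adjust_forecast,
    assign_states,
    divide_states,
    predict_state,
    transition_model,
)
from greymarkov.synthetic import SyntheticSpec, generate_state_series


def path_of(states, m=4):
    space = StateSpace(tuple(np.linspace(0.5, 1.5, m + 1)))
    return StatePath(states=tuple(states), space=space)


class TestDivideStates:
    def test_fixed_boundaries_reproduce_published_bands(self):
        space = divide_states([], method="fixed",
                              boundaries=(0.60, 0.75, 0.90, 1.05, 1.20))
        assert space.m == 4
        assert space.interval(1) == (0.60, 0.75)
        assert space.interval(4) == (1.05, 1.20)

    def test_equal_width_on_exact_span_matches_fixed(self):
        ratios = np.linspace(0.60, 1.20, 13)
        space = divide_states(ratios, m=4, method="equal_width")
        np.testing.assert_allclose(space.boundaries,
                                   (0.60, 0.75, 0.90, 1.05, 1.20))

    def test_single_state_covers_all_ratios(self):
        ratios = [0.8, 0.9, 1.1]
        space = divide_states(ratios, m=1, method="cluster")
        assert space.m == 1
        assert space.boundaries[0] <= min(ratios)
        assert space.boundaries[-1] >= max(ratios)

    def test_cluster_separates_well_separated_groups(self):
        ratios = [0.70, 0.71, 0.72, 1.00, 1.01, 1.02, 1.30, 1.31]
        space = divide_states(ratios, m=3, method="cluster")
        path = assign_states(ratios, space)
        assert path.states == (1, 1, 1, 2, 2, 2, 3, 3)

    def test_more_states_than_distinct_ratios_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            divide_states([1.0, 1.0, 1.1], m=3, method="cluster")


class TestAssignStates:
    @pytest.fixture
    def published(self):
        return StateSpace((0.60, 0.75, 0.90, 1.05, 1.20))

    def test_published_examples(self, published):
        assert assign_states([0.84], published).states == (2,)
        assert assign_states([1.11], published).states == (4,)

    def test_half_open_boundary_goes_up(self, published):
        assert assign_states([0.90], published).states == (3,)

    def test_top_boundary_closed(self, published):
        assert assign_states([1.20], published).states == (4,)

    def test_out_of_range_clipped_with_warning(self, published):
        with pytest.warns(UserWarning, match="clipped"):
            path = assign_states([0.10, 1.50], published)
        assert path.states == (1, 4)


class TestTransitionModel:
    def test_self_loop_path(self):
        tm = transition_model(path_of([1, 1, 1]), step=1)
        assert tm.probabilities[0, 0] == 1.0

    def test_alternating_path_counts(self):
        tm = transition_model(path_of([1, 2, 1, 2]), step=1)
        assert tm.counts[0, 1] == 2 and tm.counts[1, 0] == 1
        assert tm.probabilities[0, 1] == 1.0
        assert tm.probabilities[1, 0] == 1.0

    def test_matrix_exports_labelled_frame(self):
        tm = transition_model(path_of([1, 2, 1, 2]), step=1)
        frame = tm.to_frame()
        assert list(frame.index) == ["E1", "E2", "E3", "E4"]
        assert frame.loc["E1", "E2"] == 1.0
        assert frame.to_csv().splitlines()[0] == ",E1,E2,E3,E4"

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            transition_model(path_of([1, 2, 1]), step=0)

    def test_counts_match_brute_force_enumeration(self):
        """Exhaustive oracle: every path of length <= 8 over 3 states."""
        m = 3
        for length in (2, 5, 8):
            for states in itertools.product(range(1, m + 1), repeat=length):
                tm = transition_model(path_of(states, m=m), step=1)
                expected = np.zeros((m, m), dtype=int)
                for i in range(length - 1):
                    expected[states[i] - 1, states[i + 1] - 1] += 1
                np.testing.assert_array_equal(tm.counts, expected)
                assert np.all(tm.counts.sum(axis=1) == tm.visits)

    def test_defined_rows_are_stochastic(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            states = rng.integers(1, 5, size=rng.integers(3, 12))
            tm = transition_model(path_of(list(states)), step=1)
            defined = tm.visits > 0
            np.testing.assert_allclose(
                tm.probabilities[defined].sum(axis=1), 1.0, atol=1e-12
            )

    def test_chapman_kolmogorov_on_long_synthetic_chain(self):
        """Empirical P(2) approximates P(1)^2 on a 10^4-step chain."""
        chain = np.array([[0.7, 0.3], [0.2, 0.8]])
        space = StateSpace((0.8, 1.0, 1.2))
        spec = SyntheticSpec(a=-0.0001, M=500.0, n=10_000, seed=11,
                             chain=chain, space=space, noise="state")
        _, path = generate_state_series(spec)
        p1 = transition_model(path, step=1).probabilities
        p2 = transition_model(path, step=2).probabilities
        assert np.max(np.abs(p2 - p1 @ p1)) < 0.05


class TestPredictState:
    def test_fixture_path_from_e4_predicts_e4(self, published_ratio_path):
        """From the case-study path through 2003 (state E4), the one-step
        argmax keeps the chain in E4."""
        truncated = StatePath(states=published_ratio_path.states[:13],
                              space=published_ratio_path.space)
        models = [transition_model(truncated, step=1)]
        assert truncated.states[-1] == 4
        assert predict_state(models, 4) == 4

    def test_tie_broken_by_two_step_matrix(self):
        p1 = transition_model(path_of([1, 2, 1, 2, 2, 1], m=2), step=1)
        # craft an explicit tie at step 1 and resolution at step 2
        from greymarkov.markov import TransitionModel
        tie = TransitionModel(step=1, counts=np.array([[1, 1], [1, 1]]),
                              visits=np.array([2, 2]),
                              probabilities=np.array([[0.5, 0.5], [0.5, 0.5]]))
        p2 = TransitionModel(step=2, counts=np.array([[1, 4], [4, 1]]),
                             visits=np.array([5, 5]),
                             probabilities=np.array([[0.2, 0.8], [0.8, 0.2]]))
        assert predict_state([tie, p2], 1) == 2

    def test_absorbing_state_stays_put(self):
        tm = transition_model(path_of([3, 3, 3, 3]), step=1)
        with pytest.warns(UserWarning):
            # rows for unvisited states fall back to uniform, but the
            # absorbing row itself is decisive
            assert predict_state([tm], 3) == 3
            assert predict_state([tm], 1) in (1, 2, 3, 4)

    def test_full_tie_prefers_nearest_then_lower(self):
        from greymarkov.markov import TransitionModel
        flat = TransitionModel(step=1, counts=np.ones((3, 3), dtype=int),
                               visits=np.full(3, 3),
                               probabilities=np.full((3, 3), 1 / 3))
        assert predict_state([flat], 2) == 2   # nearest to current
        assert predict_state([flat], 1) == 1


class TestAdjustForecast:
    def test_published_2004_adjustment(self):
        space = StateSpace((0.60, 0.75, 0.90, 1.05, 1.20))
        adj = adjust_forecast(5433, 4, space)
        assert adj.adjusted_ratio == pytest.approx(1.125)
        assert adj.rounded == 6112

    def test_degenerate_interval_is_identity(self):
        space = StateSpace((0.5, 1.0, 1.0 + 1e-9))
        adj = adjust_forecast(100.0, 1, space)
        assert adj.adjusted_value == pytest.approx(100.0 * 0.75)

    def test_midpoint_identity_with_offsets(self):
        space = StateSpace((0.60, 0.75, 0.90, 1.05, 1.20))
        for y in (0.7, 1.0, 1.19):
            a_off, b_off = space.offsets(y, 4)
            assert y + (a_off + b_off) / 2 == pytest.approx(space.midpoint(4))

    def test_adjusted_value_always_inside_band_times_base(self):
        rng = np.random.default_rng(3)
        space = StateSpace((0.60, 0.75, 0.90, 1.05, 1.20))
        for _ in range(100):
            base = rng.uniform(10, 1e4)
            state = int(rng.integers(1, 5))
            adj = adjust_forecast(base, state, space)
            lo, hi = space.interval(state)
            assert base * lo <= adj.adjusted_value <= base * hi

    def test_nonpositive_base_rejected(self):
        space = StateSpace((0.5, 1.5))
        with pytest.raises(ValueError):
            adjust_forecast(0.0, 1, space)
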