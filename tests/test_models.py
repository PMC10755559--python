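"""Unit and property tests of the Q-learning family and its likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import prlkit as pk
from prlkit.models import MODEL_REGISTRY, LearnerState, get_model

from _oracle import random_trial_log, step_through
from conftest import make_params


class TestRegistry:
    def test_six_models(self):
        assert len(MODEL_REGISTRY) == 6
        assert sorted(MODEL_REGISTRY) == [1, 2, 3, 4, 5, 6]

    def test_winning_model_has_five_free_parameters(self):
        m6 = get_model(6)
        assert m6.split_learning_rates
        assert m6.use_stim_stickiness and m6.use_side_stickiness
        assert m6.free_params == ("alpha_rew", "alpha_pun", "beta",
                                  "kappa_stim", "kappa_side")
        assert m6.n_free == 5

    def test_unknown_model_id(self):
        with pytest.raises(KeyError):
            get_model(7)

    def test_constrain_nulls_absent_parameters(self):
        p = make_params(alpha=0.3, alpha_pun=0.7, kappa_stim=1.0, kappa_side=-1.0)
        c = get_model(1).constrain(p)
        assert c.alpha_pun == c.alpha_rew == 0.3
        assert c.kappa_stim == 0.0 and c.kappa_side == 0.0


class TestUpdateQ:
    @pytest.mark.parametrize("q, alpha, r, expected", [
        (0.5, 0.2, 1, 0.6),   # one step toward reward
        (0.5, 0.0, 1, 0.5),   # zero learning rate freezes values
        (0.5, 0.0, 0, 0.5),
        (0.5, 1.0, 0, 0.0),   # full update lands on the outcome
    ])
    def test_update_arithmetic(self, q, alpha, r, expected):
        state = LearnerState(q_values={"A": q, "B": 0.5})
        p = make_params(alpha=alpha, alpha_pun=alpha)
        out = pk.update_q(state, "A", "left", r, p)
        assert out.q_values["A"] == pytest.approx(expected)
        assert out.q_values["B"] == 0.5  # unchosen untouched
        assert out.prev_stim == "A" and out.prev_side == "left"

    def test_learning_rate_selected_by_outcome(self):
        state = LearnerState(q_values={"A": 0.5, "B": 0.5})
        p = make_params(alpha=0.2, alpha_pun=0.8)
        assert pk.update_q(state, "A", "left", 1, p).q_values["A"] == pytest.approx(0.6)
        assert pk.update_q(state, "A", "left", 0, p).q_values["A"] == pytest.approx(0.1)

    def test_invalid_reinforcement(self):
        state = LearnerState(q_values={"A": 0.5, "B": 0.5})
        with pytest.raises(ValueError):
            pk.update_q(state, "A", "left", 2, make_params())

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=60),
           st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_q_values_stay_in_unit_interval(self, seq, a_rew, a_pun):
        state = LearnerState(q_values={"A": 0.5, "B": 0.5})
        p = pk.ParameterSet(a_rew, a_pun, 1.0)
        for choice, r in seq:
            stim = "A" if choice == 0 else "B"
            state = pk.update_q(state, stim, "left", r, p)
            assert all(0.0 <= q <= 1.0 for q in state.q_values.values())


class TestChoiceProbability:
    def test_symmetry_at_equal_values(self):
        state = LearnerState(q_values={"A": 0.4, "B": 0.4})
        assert pk.choice_probability(state, "A", "B", make_params(beta=7.3)) == 0.5

    def test_value_driven_choice(self):
        # logistic(2 * (0.8 - 0.2)) = logistic(1.2)
        state = LearnerState(q_values={"A": 0.8, "B": 0.2})
        p = make_params(beta=2.0)
        assert pk.choice_probability(state, "A", "B", p) == pytest.approx(
            0.768524783499018, abs=1e-12)

    def test_stickiness_driven_choice(self):
        # logistic(1) with beta = 0 and previous stimulus on the left
        state = LearnerState(q_values={"A": 0.9, "B": 0.1}, prev_stim="A")
        p = make_params(beta=0.0, kappa_stim=1.0)
        assert pk.choice_probability(state, "A", "B", p) == pytest.approx(
            0.731058578630005, abs=1e-12)

    def test_no_history_indicators_are_zero(self):
        state = LearnerState(q_values={"A": 0.5, "B": 0.5})
        p = make_params(beta=0.0, kappa_stim=50.0, kappa_side=50.0)
        assert pk.choice_probability(state, "A", "B", p) == 0.5

    def test_stimulus_swap_complements(self):
        # P(choose A | A left) + P(choose B | B left) = 1 when only
        # stimulus-bound terms (values, stimulus stickiness) are active
        state = LearnerState(q_values={"A": 0.7, "B": 0.3},
                             prev_stim="B", prev_side=None)
        p = make_params(beta=1.5, kappa_stim=0.4)
        pl = pk.choice_probability(state, "A", "B", p)
        pr = pk.choice_probability(state, "B", "A", p)
        assert pl + pr == pytest.approx(1.0, abs=1e-12)

    def test_stickiness_monotonically_favours_repeats(self):
        state = LearnerState(q_values={"A": 0.3, "B": 0.7},
                             prev_stim="A", prev_side="left")
        probs = [pk.choice_probability(state, "A", "B",
                                       make_params(beta=1.0, kappa_stim=k))
                 for k in np.linspace(0.0, 3.0, 7)]
        assert np.all(np.diff(probs) > 0)


def _df(rows):
    return pd.DataFrame(rows)


class TestSequenceLogLikelihood:
    def test_single_trial_indifference(self):
        rows = random_trial_log(np.random.default_rng(0), n_trials=1, n_blocks=1)
        ll = pk.sequence_log_likelihood(_df(rows), make_params(beta=5.0),
                                        get_model(6))
        assert ll == pytest.approx(math.log(0.5))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_step_through_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = random_trial_log(rng, n_trials=int(rng.integers(2, 15)))
        p = pk.ParameterSet(*rng.uniform([0, 0, 0, -1, -1], [1, 1, 8, 1, 1]))
        ll = pk.sequence_log_likelihood(_df(rows), p, get_model(6))
        expected, _ = step_through(rows, p.alpha_rew, p.alpha_pun, p.beta,
                                   p.kappa_stim, p.kappa_side)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_nesting_model6_reduces_to_model1(self):
        rows = random_trial_log(np.random.default_rng(3), n_trials=20)
        p = make_params(alpha=0.3, beta=2.0)
        ll6 = pk.sequence_log_likelihood(_df(rows), p, get_model(6))
        ll1 = pk.sequence_log_likelihood(_df(rows), p, get_model(1))
        assert ll6 == ll1

    def test_perfect_repetition_limit(self):
        # huge stimulus stickiness, subject always repeats: loglik -> ~0
        rows = random_trial_log(np.random.default_rng(4), n_trials=30, n_blocks=1)
        first = rows[0]["choice_stim"]
        for row in rows:
            row["choice_stim"] = first
            row["choice_side"] = "left" if row["stim_left"] == first else "right"
        p = make_params(beta=0.0, kappa_stim=400.0)
        ll = pk.sequence_log_likelihood(_df(rows), p, get_model(2))
        # every repeat has probability ~1; only the first trial is uncertain
        assert ll == pytest.approx(math.log(0.5), abs=1e-9)

    def test_rejects_unsorted_trials(self):
        rows = random_trial_log(np.random.default_rng(5), n_trials=5, n_blocks=1)
        df = _df(rows).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            pk.sequence_log_likelihood(df, make_params(), get_model(1))

    def test_rejects_duplicate_trials(self):
        rows = random_trial_log(np.random.default_rng(6), n_trials=5, n_blocks=1)
        df = _df(rows + [rows[-1]])
        with pytest.raises(ValueError, match="duplicate"):
            pk.sequence_log_likelihood(df, make_params(), get_model(1))

    def test_block_reset_switch_changes_likelihood(self):
        rows = random_trial_log(np.random.default_rng(7), n_trials=10,
                                n_blocks=2, shared_stimuli=True)
        p = make_params(alpha=0.5, beta=4.0, kappa_stim=0.5)
        ll_reset = pk.sequence_log_likelihood(_df(rows), p, get_model(6))
        ll_carry = pk.sequence_log_likelihood(_df(rows), p, get_model(6),
                                              reset_between_blocks=False)
        oracle_carry, _ = step_through(rows, p.alpha_rew, p.alpha_pun, p.beta,
                                       p.kappa_stim, p.kappa_side,
                                       reset_between_blocks=False)
        assert ll_carry == pytest.approx(oracle_carry, abs=1e-10)
        assert ll_reset != ll_carry


class TestParameterSet:
    @pytest.mark.parametrize("kwargs", [
        dict(alpha_rew=-0.1, alpha_pun=0.5, beta=1.0),
        dict(alpha_rew=0.5, alpha_pun=1.2, beta=1.0),
        dict(alpha_rew=0.5, alpha_pun=0.5, beta=-0.5),
    ])
    def test_domain_validation(self, kwargs):
        with pytest.raises(ValueError):
            pk.ParameterSet(**kwargs)
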