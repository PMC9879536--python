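"""Hybrid model: transforms, policies, updates, likelihood, simulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import twostep as ts
from twostep.model import ValueState
from twostep.task import TrialRecord


def _params(**kw) -> ts.AgentParameters:
    base = dict(beta_MB=1.0, beta_MF=1.0, beta_2=1.0,
                alpha_1=0.5, alpha_2=0.5, lam=0.5, p_rep=0.0)
    base.update(kw)
    return ts.AgentParameters(**base)


class TestTransforms:
    def test_midpoint_values_map_to_zero(self):
        vec = ts.to_unbounded(_params(beta_MB=1, beta_MF=1, beta_2=1,
                                      alpha_1=0.5, alpha_2=0.5, lam=0.5))
        np.testing.assert_allclose(vec, 0.0, atol=1e-12)

    def test_zero_vector_maps_to_unit_betas_and_half_rates(self):
        p = ts.to_native(np.zeros(7))
        assert p.beta_MB == p.beta_MF == p.beta_2 == pytest.approx(1.0)
        assert p.alpha_1 == p.alpha_2 == p.lam == pytest.approx(0.5)
        assert p.p_rep == 0.0

    def test_logit_of_059(self):
        vec = ts.to_unbounded(_params(alpha_2=0.59))
        assert vec[4] == pytest.approx(np.log(0.59 / 0.41), abs=1e-10)
        assert vec[4] == pytest.approx(0.3640, abs=5e-4)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_round_trip_identity(self, seed):
        vec = np.random.default_rng(seed).normal(0, 2, 7)
        back = ts.to_unbounded(ts.to_native(vec))
        np.testing.assert_allclose(back, vec, atol=1e-10)

    def test_extreme_logit_saturates_without_overflow(self):
        vec = np.zeros(7)
        vec[3] = 30.0
        p = ts.to_native(vec)
        assert p.alpha_1 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("kw", [
        {"alpha_1": 0.0}, {"alpha_1": 1.0}, {"lam": 1.0}, {"beta_MB": 0.0},
    ])
    def test_boundary_values_rejected_by_transform(self, kw):
        with pytest.raises(ValueError):
            ts.to_unbounded(_params(**kw))

    def test_non_finite_vector_rejected(self):
        with pytest.raises(ValueError):
            ts.to_native([0, 0, np.inf, 0, 0, 0, 0])


class TestModelBasedValues:
    def test_zero_values_back_up_to_zero(self, task):
        np.testing.assert_array_equal(
            ts.model_based_values(np.zeros((2, 2)), task), [0.0, 0.0]
        )

    def test_bellman_backup_hand_example(self, task):
        q2 = np.array([[1.0, 0.0], [0.0, 0.0]])
        np.testing.assert_allclose(
            ts.model_based_values(q2, task), [0.7, 0.3], atol=1e-12
        )

    def test_identical_states_give_symmetric_values(self, task):
        q2 = np.array([[0.2, 0.6], [0.2, 0.6]])
        v = ts.model_based_values(q2, task)
        assert v[0] == pytest.approx(v[1])


class TestPolicies:
    def test_indifferent_agent_is_uniform(self, task):
        state = ValueState()
        p = ts.stage1_policy(state, _params(beta_MB=0, beta_MF=0), task)
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_stage1_softmax_hand_example(self, task):
        state = ValueState(Q1_MF=np.array([1.0, 0.0]))
        p = ts.stage1_policy(state, _params(beta_MB=0, beta_MF=1), task)
        e = np.exp(1.0)
        np.testing.assert_allclose(p, [e / (e + 1), 1 / (e + 1)], atol=1e-12)

    def test_strong_perseveration_repeats_previous_choice(self, task):
        state = ValueState(prev_choice1=0)
        last = 0.5
        for rep in [1.0, 5.0, 20.0]:
            p = ts.stage1_policy(state, _params(beta_MB=0, beta_MF=0, p_rep=rep), task)
            assert p[0] > last  # monotone approach to 1
            last = p[0]
        assert last > 0.999

    def test_stage2_softmax_hand_example(self):
        state = ValueState(Q2=np.array([[0.75, 0.25], [0.0, 0.0]]))
        p = ts.stage2_policy(state, 0, _params(beta_2=2.0))
        expected = np.exp([1.5, 0.5]) / np.exp([1.5, 0.5]).sum()
        np.testing.assert_allclose(p, expected, atol=1e-12)

    def test_zero_temperature_uniform_stage2(self):
        state = ValueState(Q2=np.array([[0.9, 0.1], [0.5, 0.5]]))
        np.testing.assert_allclose(
            ts.stage2_policy(state, 0, _params(beta_2=0.0)), [0.5, 0.5]
        )

    def test_higher_beta2_sharpens_towards_better_action(self):
        state = ValueState(Q2=np.array([[0.7, 0.3], [0.0, 0.0]]))
        probs = [ts.stage2_policy(state, 0, _params(beta_2=b))[0]
                 for b in [0.5, 1, 2, 5, 20]]
        assert all(a < b for a, b in zip(probs, probs[1:]))
        assert probs[-1] > 0.999

    @settings(max_examples=200, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_policies_are_normalized_probabilities(self, task, seed):
        rng = np.random.default_rng(seed)
        state = ValueState(Q1_MF=rng.uniform(0, 1, 2), Q2=rng.uniform(0, 1, (2, 2)),
                           prev_choice1=int(rng.integers(0, 2)))
        p = ts.to_native(rng.normal(0, 2, 7))
        for probs in (ts.stage1_policy(state, p, task),
                      ts.stage2_policy(state, int(rng.integers(0, 2)), p)):
            assert np.all(probs > 0)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestUpdates:
    def test_zero_learning_rates_freeze_values(self):
        state = ValueState(Q1_MF=np.array([0.3, 0.4]), Q2=np.full((2, 2), 0.2))
        trial = TrialRecord(choice1=1, transition="common", state2=1, choice2=0, reward=1)
        new, _ = ts.update_values(state, trial, _params(alpha_1=0, alpha_2=0))
        np.testing.assert_array_equal(new.Q1_MF, state.Q1_MF)
        np.testing.assert_array_equal(new.Q2, state.Q2)
        assert new.prev_choice1 == 1

    def test_hand_computed_prediction_errors_and_updates(self):
        # Q1=0.5, Q2=0.4, r=1, alpha=0.5, lam=0.5:
        # delta1 = -0.1, delta2 = 0.6, Q1 -> 0.60, Q2 -> 0.70
        state = ValueState(Q1_MF=np.array([0.5, 0.0]),
                           Q2=np.array([[0.4, 0.0], [0.0, 0.0]]))
        trial = TrialRecord(choice1=0, transition="common", state2=0, choice2=0, reward=1)
        new, trace = ts.update_values(state, trial,
                                      _params(alpha_1=0.5, alpha_2=0.5, lam=0.5))
        assert trace.delta1 == pytest.approx(-0.1)
        assert trace.delta2 == pytest.approx(0.6)
        assert new.Q1_MF[0] == pytest.approx(0.60)
        assert new.Q2[0, 0] == pytest.approx(0.70)

    def test_full_learning_rate_and_eligibility_copy_reward(self):
        rng = np.random.default_rng(4)
        state = ValueState(Q1_MF=rng.uniform(0, 1, 2), Q2=rng.uniform(0, 1, (2, 2)))
        trial = TrialRecord(choice1=0, transition="common", state2=0, choice2=1, reward=1)
        new, _ = ts.update_values(state, trial, _params(alpha_1=1.0, lam=1.0))
        assert new.Q1_MF[0] == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_q_values_stay_in_unit_interval(self, task, seed):
        """New Q1 is a convex combination of old Q1, Q2 and the reward."""
        rng = np.random.default_rng(seed)
        p = ts.AgentParameters(
            beta_MB=rng.uniform(0, 5), beta_MF=rng.uniform(0, 5),
            beta_2=rng.uniform(0, 5), alpha_1=rng.uniform(0, 1),
            alpha_2=rng.uniform(0, 1), lam=rng.uniform(0, 1),
            p_rep=rng.normal(0, 1),
        )
        state = ValueState()
        for _ in range(200):
            a1 = int(rng.integers(0, 2))
            s2, label = ts.sample_transition(task, a1, rng)
            trial = TrialRecord(choice1=a1, transition=label, state2=s2,
                                choice2=int(rng.integers(0, 2)),
                                reward=int(rng.integers(0, 2)))
            state, _ = ts.update_values(state, trial, p)
            assert np.all(state.Q1_MF >= 0) and np.all(state.Q1_MF <= 1)
            assert np.all(state.Q2 >= 0) and np.all(state.Q2 <= 1)


class TestSessionLogLikelihood:
    def test_random_policy_likelihood_is_closed_form(self, task, small_session):
        frame, _ = small_session
        p = _params(beta_MB=0, beta_MF=0, beta_2=0, p_rep=0)
        ll, p1 = ts.session_log_likelihood(p, frame, task)
        assert ll == pytest.approx(2 * len(frame) * np.log(0.5))
        np.testing.assert_allclose(p1, 0.5)

    def test_matches_straight_line_reimplementation(self, task, mixed_agent,
                                                    small_session):
        """Exact agreement with an independent step-by-step recomputation."""
        frame, _ = small_session
        ll, p1 = ts.session_log_likelihood(mixed_agent, frame, task)

        # straight-line oracle: explicit softmaxes and updates, no shared code
        pc = task.p_common
        b_mb, b_mf, b2 = mixed_agent.beta_MB, mixed_agent.beta_MF, mixed_agent.beta_2
        a1r, a2r, lam, rep = (mixed_agent.alpha_1, mixed_agent.alpha_2,
                              mixed_agent.lam, mixed_agent.p_rep)
        q1 = [0.0, 0.0]
        q2 = [[0.0, 0.0], [0.0, 0.0]]
        prev = None
        total = 0.0
        p1_oracle = []
        for row in frame.itertuples():
            qmb = [pc * max(q2[0]) + (1 - pc) * max(q2[1]),
                   (1 - pc) * max(q2[0]) + pc * max(q2[1])]
            v = [b_mf * q1[a] + b_mb * qmb[a] + (rep if prev == a else 0.0)
                 for a in (0, 1)]
            z = np.exp(np.array(v) - max(v))
            pi1 = z / z.sum()
            w = np.exp(b2 * np.array(q2[row.state2]) - max(b2 * np.array(q2[row.state2])))
            pi2 = w / w.sum()
            total += np.log(max(pi1[row.choice1], 1e-12))
            total += np.log(max(pi2[row.choice2], 1e-12))
            p1_oracle.append(pi1[row.choice1])
            d1 = q2[row.state2][row.choice2] - q1[row.choice1]
            d2 = row.reward - q2[row.state2][row.choice2]
            q1[row.choice1] += a1r * d1 + a1r * lam * d2
            q2[row.state2][row.choice2] += a2r * d2
            prev = row.choice1
        assert ll == pytest.approx(total, abs=1e-10)
        np.testing.assert_allclose(p1, p1_oracle, atol=1e-12)

    def test_unsorted_trials_rejected(self, task, mixed_agent, small_session):
        frame, _ = small_session
        shuffled = frame.sample(frac=1.0, random_state=0)
        with pytest.raises(ValueError):
            ts.session_log_likelihood(mixed_agent, shuffled, task)

    def test_gap_in_trials_rejected(self, task, mixed_agent, small_session):
        frame, _ = small_session
        gappy = frame[frame["trial"] != 5]
        with pytest.raises(ValueError):
            ts.session_log_likelihood(mixed_agent, gappy, task)


class TestSimulator:
    def test_session_layout_and_determinism(self, task, mixed_agent):
        f1, w1 = ts.simulate_agent(mixed_agent, task, seed=11)
        f2, _ = ts.simulate_agent(mixed_agent, task, seed=11)
        assert len(f1) == task.n_sessions * task.n_trials_per_session
        assert len(w1) == task.n_sessions
        assert f1.equals(f2)

    def test_uniform_agent_near_half_stay_in_all_cells(self, task):
        p = _params(beta_MB=0, beta_MF=0, beta_2=0, p_rep=0)
        cfg = ts.TaskConfig(n_trials_per_session=2000, n_sessions=1)
        frame, _ = ts.simulate_agent(p, cfg, seed=2)
        stay = ts.stay_probability_analysis(frame)
        assert np.all(np.abs(stay.group_means.to_numpy() - 0.5) < 0.06)

    def test_agent_predicts_its_own_choices_above_chance(self, task):
        """Likelihood/simulator consistency over a small parameter grid."""
        for b_mb, b_mf, rep in [(2, 0, 0), (0, 2, 0), (0, 0, 1.5), (1, 1, 0.5)]:
            p = _params(beta_MB=b_mb, beta_MF=b_mf, p_rep=rep)
            frame, _ = ts.simulate_agent(p, task, seed=13, session=1)
            _, p1 = ts.session_log_likelihood(p, frame, task)
            assert p1.mean() > 0.5
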