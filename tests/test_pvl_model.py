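import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvl_igt import igt_task as it
from pvl_igt import pvl_model as pm

from conftest import brute_force_loglik

params_strategy = st.tuples(
    st.floats(0.01, 1.0),
    st.floats(0.0, 5.0),
    st.floats(0.0, 1.0),
    st.floats(0.0, 5.0),
)


class TestUtility:
    def test_linear_identity_when_a_and_lambda_are_one(self):
        for x in (-1250.0, -50.0, 0.0, 50.0, 100.0):
            assert pm.utility(x, 1.0, 1.0) == x

    def test_zero_outcome_zero_valence(self):
        assert pm.utility(0.0, 0.5, 3.0) == 0.0
        assert pm.utility(0.0, 0.0, 3.0) == 0.0  # 0^0 routed to the zero branch

    def test_large_loss_at_group_mean_parameters(self):
        assert pm.utility(-1250, 0.249, 0.355) == pytest.approx(
            -0.355 * 1250**0.249, rel=1e-12
        )

    @given(st.floats(0.01, 1.0), st.floats(0.0, 5.0),
           st.floats(-2000, 2000), st.floats(-2000, 2000))
    def test_monotone_in_outcome(self, a, lam, x1, x2):
        lo, hi = sorted((x1, x2))
        assert pm.utility(lo, a, lam) <= pm.utility(hi, a, lam) + 1e-12

    @given(st.floats(0.01, 1.0), st.floats(-2000, -0.01),
           st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    def test_loss_aversion_scales_losses_only(self, a, x, l1, l2):
        lo, hi = sorted((l1, l2))
        assert pm.utility(x, a, hi) <= pm.utility(x, a, lo)
        assert pm.utility(-x, a, hi) == pm.utility(-x, a, lo)

    def test_lambda_zero_ignores_losses(self):
        for x in (-1250.0, -250.0, -1.0):
            assert pm.utility(x, 0.5, 0.0) == 0.0


class TestExpectancyUpdate:
    def test_zero_state_credits_chosen_deck(self):
        s = pm.update_expectancies(pm.ExpectancyState(), "B", -2.0, 0.5)
        assert s.E.tolist() == [0, -2, 0, 0] and s.t == 1

    def test_identity_at_full_retention_zero_valence(self):
        s0 = pm.ExpectancyState(np.array([1.0, 2, 3, 4]))
        assert pm.update_expectancies(s0, "A", 0.0, 1.0).E.tolist() == [1, 2, 3, 4]

    def test_decay_and_credit(self):
        s0 = pm.ExpectancyState(np.array([1.0, 2, 3, 4]))
        assert pm.update_expectancies(s0, "C", 10.0, 0.5).E.tolist() == [0.5, 1, 11.5, 2]

    def test_memoryless_at_zero_retention(self):
        s0 = pm.ExpectancyState(np.array([5.0, -3, 2, 7]))
        s1 = pm.update_expectancies(s0, "D", 1.5, 0.0)
        assert s1.E.tolist() == [0, 0, 0, 1.5]

    def test_running_sum_at_full_retention(self):
        s = pm.ExpectancyState()
        for u in (1.0, 2.0, 3.0):
            s = pm.update_expectancies(s, "A", u, 1.0)
        assert s.E[0] == 6.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pm.update_expectancies(pm.ExpectancyState(), "A", 1.0, 1.5)
        with pytest.raises(KeyError):
            pm.update_expectancies(pm.ExpectancyState(), "E", 1.0, 0.5)


class TestChoiceRule:
    def test_theta_values(self):
        assert pm.consistency_theta(0.0) == 0.0
        assert pm.consistency_theta(1.0) == 2.0
        assert pm.consistency_theta(2.0, t=10, rule="trial_dependent") == 1.0

    def test_uniform_at_zero_consistency(self):
        s = pm.ExpectancyState(np.array([3.0, -1, 0.5, 2]))
        assert pm.choice_probabilities(s, 0.0).tolist() == [0.25] * 4

    def test_uniform_for_equal_expectancies(self):
        s = pm.ExpectancyState(np.ones(4))
        np.testing.assert_allclose(pm.choice_probabilities(s, 3.0), 0.25)

    def test_softmax_against_closed_form(self):
        s = pm.ExpectancyState(np.array([1.0, 0, 0, 0]))
        p = pm.choice_probabilities(s, 1.0)  # theta = 2
        e2 = math.e**2
        np.testing.assert_allclose(p, [e2 / (e2 + 3)] + [1 / (e2 + 3)] * 3, rtol=1e-12)

    def test_no_overflow_for_extreme_state(self):
        s = pm.ExpectancyState(np.array([4000.0, 0, 0, 0]))
        p = pm.choice_probabilities(s, 5.0)
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)

    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=4), st.floats(0, 5))
    def test_probabilities_normalise(self, E, c):
        p = pm.choice_probabilities(pm.ExpectancyState(np.array(E)), c)
        assert abs(p.sum() - 1.0) < 1e-12 and (p >= 0).all()


class TestSimulateAgent:
    def test_same_seed_identical_sequences(self):
        p = pm.PVLParameters(0.3, 1.0, 0.5, 1.0)
        s1 = pm.simulate_agent(p, seed=7)
        s2 = pm.simulate_agent(p, seed=7)
        assert (s1.decks == s2.decks).all() and (s1.losses == s2.losses).all()

    def test_zero_consistency_uniform_deck_frequencies(self):
        p = pm.PVLParameters(0.3, 1.0, 0.5, 0.0)
        seq = pm.simulate_agent(p, n_trials=10_000, seed=11)
        freqs = np.bincount(seq.decks, minlength=4) / 10_000
        se = np.sqrt(0.25 * 0.75 / 10_000)
        assert np.all(np.abs(freqs - 0.25) < 3 * se + 1e-9)

    def test_high_consistency_perseverates_after_big_win(self):
        """With c=5 and full retention, one big deck-D win locks in deck D."""
        from pvl_igt import synthetic_data as sd

        sched = it.PayoffSchedule(
            decks={
                "A": it.DeckSchedule(1.0, 0, 0.0),
                "B": it.DeckSchedule(1.0, 0, 0.0),
                "C": it.DeckSchedule(1.0, 0, 0.0),
                "D": it.DeckSchedule(1000.0, 0, 0.0),
            }
        )
        n = 1000
        rng = np.random.default_rng(5)
        ones = np.ones(n)
        decks, _, _ = sd.simulate_agents_batch(
            ones, ones, ones, 5 * ones, 30, rng, sched
        )
        fracs = []
        for row in decks:
            first_d = np.argmax(row == 3)
            if (row == 3).any() and first_d < 29:
                rest = row[first_d + 1 :]
                fracs.append((rest == 3).mean())
        assert np.mean(fracs) > 0.95

    def test_practice_and_task_layout(self):
        p = pm.PVLParameters(0.3, 1.0, 0.5, 1.0)
        df = pm.simulate_practice_and_task(p, seed=3)
        assert len(df) == 120
        assert df["is_practice"].sum() == 20
        assert df["trial"].tolist() == list(range(1, 121))
        np.testing.assert_allclose(df["net"], df["gain"] + df["loss"])


class TestLogLikelihood:
    def test_single_trial_is_log_quarter(self):
        seq = pm.ChoiceSequence(decks=[2], gains=[50.0], losses=[0.0])
        p = pm.PVLParameters(0.7, 2.0, 0.3, 4.0)
        assert pm.log_likelihood(seq, p) == pytest.approx(np.log(0.25), abs=1e-12)

    def test_zero_consistency_is_uniform(self):
        p0 = pm.PVLParameters(0.3, 1.0, 0.5, 0.0)
        seq = pm.simulate_agent(pm.PVLParameters(0.3, 1.0, 0.5, 1.0), seed=9, n_trials=73)
        assert pm.log_likelihood(seq, p0) == pytest.approx(73 * np.log(0.25), abs=1e-9)

    def test_matches_independent_recomputation_small_grid(self):
        """Recursion agrees with the naive trial-by-trial oracle to 1e-10."""
        rng = np.random.default_rng(21)
        sched = it.build_default_schedule()
        for rule in ("as_printed", "trial_dependent"):
            for _ in range(60):
                params = (
                    rng.uniform(0.01, 1),
                    rng.uniform(0, 5),
                    rng.uniform(0, 1),
                    rng.uniform(0, 2),
                )
                n = int(rng.integers(1, 11))
                gen = pm.PVLParameters(0.3, 1.0, 0.5, 0.8)
                seq = pm.simulate_agent(gen, sched, n, seed=int(rng.integers(2**31)))
                expected = brute_force_loglik(
                    seq.deck_letters, seq.nets, *params, rule=rule
                )
                got = pm.log_likelihood(seq, pm.PVLParameters(*params), rule)
                assert got == pytest.approx(expected, abs=1e-10)

    def test_generating_parameters_beat_perturbed(self):
        """Mean log-likelihood is highest near the generating parameters."""
        truth = pm.PVLParameters(0.3, 1.0, 0.5, 1.0)
        seqs = [pm.simulate_agent(truth, seed=i, n_trials=100) for i in range(200)]
        ll_true = np.mean([pm.log_likelihood(s, truth) for s in seqs])
        for d_A, d_c in ((0.3, 0), (-0.3, 0), (0, 0.3), (0, -0.3)):
            pert = pm.PVLParameters(0.3, 1.0, 0.5 + d_A, 1.0 + d_c)
            ll_pert = np.mean([pm.log_likelihood(s, pert) for s in seqs])
            assert ll_true > ll_pert

    def test_batch_matches_scalar(self):
        gen = pm.PVLParameters(0.25, 0.5, 0.45, 0.6)
        seqs = [pm.simulate_agent(gen, seed=40 + i, n_trials=50) for i in range(5)]
        mat = np.array([[0.3, 1.0, 0.5, 1.0], [0.25, 0.5, 0.45, 0.6]])
        out = pm.log_likelihood_many(seqs, mat, subject_index=[0, 3])
        assert out[0] == pytest.approx(pm.log_likelihood(seqs[0], pm.PVLParameters(*mat[0])))
        assert out[1] == pytest.approx(pm.log_likelihood(seqs[3], pm.PVLParameters(*mat[1])))

    def test_out_of_range_parameters_rejected(self):
        seq = pm.ChoiceSequence(decks=[0], gains=[100.0], losses=[0.0])
        with pytest.raises(ValueError):
            pm.log_likelihood(seq, (1.5, 1.0, 0.5, 1.0))

    def test_frame_roundtrip(self):
        gen = pm.PVLParameters(0.3, 1.0, 0.5, 1.0)
        seq = pm.simulate_agent(gen, seed=2, n_trials=100, subject_id="s7")
        back = pm.ChoiceSequence.from_frame(seq.to_frame())
        assert (back.decks == seq.decks).all()
        assert back.subject_id == "s7"
        assert pm.log_likelihood(back, gen) == pm.log_likelihood(seq, gen)
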