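import numpy as np
import pytest

from beliefpupil import learner, normative
from beliefpupil.task import TaskConfig, generate_session

from oracles import enumerate_posterior


def grid_for(params: learner.LearnerParams, n_grid: int = 50) -> learner.PosteriorGrid:
    return learner.init_grid(params, n_grid)


class TestInitGrid:
    def test_wide_reference_prior_is_flat(self):
        g = learner.init_grid(learner.LearnerParams(mu=0.5, phi=2.0), 50)
        np.testing.assert_allclose(g.prior0, 1.0 / 50, atol=1e-12)

    def test_grid_prior_mean_matches_beta_mean(self):
        g = learner.init_grid(learner.LearnerParams(mu=0.3, phi=20.0), 200)
        assert g.h @ g.prior0 == pytest.approx(0.3, abs=1e-3)

    def test_joint_is_normalized_with_uniform_sources(self):
        g = learner.init_grid(learner.LearnerParams(mu=0.4, phi=5.0), 100)
        assert g.joint.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(g.joint[:, 0], g.joint[:, 1])

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            learner.LearnerParams(mu=0.5, phi=0.0)
        with pytest.raises(ValueError):
            learner.init_grid(learner.LearnerParams(mu=0.5, phi=2.0), 10)


class TestStep:
    def test_symmetric_state_surprisal_is_ln2(self):
        params = learner.LearnerParams(mu=0.5, phi=2.0)
        g = learner.init_grid(params, 50)
        for tone in (0, 1):
            _, psi, surprisal = learner.step(g, tone, params)
            assert psi == pytest.approx(0.0, abs=1e-12)
            assert surprisal == pytest.approx(np.log(2), abs=1e-12)

    def test_step_and_run_agree(self, mixed_session):
        params = learner.LearnerParams(mu=0.4, phi=5.0, K=0.05)
        tones = mixed_session.tone[:50]
        g = learner.init_grid(params, 50)
        psis = []
        surps = []
        for tone in tones:
            g, psi, surprisal = learner.step(g, int(tone), params)
            psis.append(psi)
            surps.append(surprisal)
        trace = learner.run(tones, params, n_grid=50)
        np.testing.assert_allclose(trace.psi, psis, atol=1e-12)
        np.testing.assert_allclose(trace.surprisal, surps, atol=1e-12)

    def test_joint_stays_normalized_through_steps(self, mixed_session):
        params = learner.LearnerParams(mu=0.3, phi=8.0, K=0.02)
        g = learner.init_grid(params, 100)
        for tone in mixed_session.tone[:200]:
            g, _, _ = learner.step(g, int(tone), params)
            assert abs(g.joint.sum() - 1.0) <= 1e-12

    @pytest.mark.parametrize("K", [0.0, 0.1])
    def test_matches_brute_force_path_enumeration(self, K, rng):
        # exhaustive sum over all 2^(T+1) source paths on an 11-point grid
        params = learner.LearnerParams(mu=0.4, phi=3.0, K=K)
        h_grid = (np.arange(11) + 0.5) / 11
        from scipy import stats as sps

        prior0 = sps.beta.pdf(h_grid, params.alpha, params.beta)
        prior0 = prior0 / prior0.sum()
        tones = rng.integers(0, 2, 10)
        g = learner.PosteriorGrid(
            h=h_grid, prior0=prior0, joint=prior0[:, None] * np.array([0.5, 0.5])
        )
        for tone in tones:
            g, _, _ = learner.step(g, int(tone), params)
        expected = enumerate_posterior(tones, h_grid, prior0, K, params.p)
        np.testing.assert_allclose(g.joint, expected, atol=1e-10)

    def test_concentrated_prior_reduces_to_fixed_hazard_model(self, mixed_session):
        # delta-like prior at the true hazard with K=0 must reproduce
        # the fixed-H normative recursion
        tones = mixed_session.tone[:1000]
        for h_true, n_grid in [(0.3, 25), (0.01, 50), (0.99, 50)]:
            params = learner.LearnerParams(mu=h_true, phi=1e6, K=0.0)
            trace = learner.run(tones, params, n_grid=n_grid)
            ref = normative.run_fixed_hazard(tones, h_true, 0.8)
            assert np.max(np.abs(trace.psi - ref.psi)) < 1e-3


class TestRun:
    def test_hazard_learning_direction_in_low_hazard_block(self):
        cfg = TaskConfig(block_schedule=[(0.01, 800)], n_trials=800, seed=4)
        s = generate_session(cfg)
        trace = learner.run(s.tone, learner.LearnerParams(mu=0.5, phi=2.0), n_grid=100)
        assert trace.posterior_mean_h[-1] < 0.2  # learned H well below the prior mean

    def test_belief_strength_is_absolute_prior_odds(self, mixed_session):
        trace = learner.run(
            mixed_session.tone[:300], learner.LearnerParams(mu=0.5, phi=2.0), 50
        )
        np.testing.assert_array_equal(trace.belief_strength, np.abs(trace.psi))

    def test_contradicting_tone_is_more_surprising(self, mixed_session):
        trace = learner.run(
            mixed_session.tone[:2000], learner.LearnerParams(mu=0.5, phi=2.0), 50
        )
        strong = trace.belief_strength > 1.0
        expected = (trace.psi > 0).astype(int)
        confirm = strong & (mixed_session.tone[:2000] == expected)
        contradict = strong & (mixed_session.tone[:2000] != expected)
        assert trace.surprisal[contradict].min() > trace.surprisal[confirm].max()

    def test_mirroring_tones_mirrors_beliefs(self, mixed_session):
        params = learner.LearnerParams(mu=0.4, phi=6.0, K=0.01)
        tones = mixed_session.tone[:500]
        a = learner.run(tones, params, 50)
        b = learner.run(1 - tones, params, 50)
        np.testing.assert_allclose(a.psi, -b.psi, atol=1e-10)
        np.testing.assert_allclose(a.surprisal, b.surprisal, atol=1e-10)

    def test_grid_resolution_stability(self):
        # at the reference configuration (K=0) the 100-point grid is
        # converged; a hazard leak keeps mass near the grid-limited
        # extremes, so only coarse stability is expected there
        cfg = TaskConfig(block_schedule=[(0.3, 1000)], n_trials=1000, seed=3)
        tones = generate_session(cfg).tone
        a = learner.run(tones, learner.LearnerParams(mu=0.5, phi=2.0), n_grid=100)
        b = learner.run(tones, learner.LearnerParams(mu=0.5, phi=2.0), n_grid=200)
        assert np.max(np.abs(a.psi - b.psi)) < 1e-3
        leaky = learner.LearnerParams(mu=0.5, phi=2.0, K=0.01)
        a = learner.run(tones, leaky, n_grid=100)
        b = learner.run(tones, leaky, n_grid=200)
        assert np.max(np.abs(a.psi - b.psi)) < 0.05

    def test_conditional_surprisal_is_expected_state_conditional_cost(self):
        params = learner.LearnerParams(mu=0.5, phi=2.0)
        g = learner.init_grid(params, 50)
        trace = learner.run(np.array([1]), params, 50)
        # symmetric predictive: 0.5 * (-ln p) + 0.5 * (-ln(1-p))
        expected = -0.5 * (np.log(0.8) + np.log(0.2))
        assert trace.surprisal_conditional[0] == pytest.approx(expected, abs=1e-12)


class TestFitLearner:
    def test_recovers_generating_parameters(self, mixed_session, rng):
        true = learner.LearnerParams(mu=0.3, phi=8.0, K=0.01, v=0.5)
        trace = learner.run(mixed_session.tone, true, n_grid=50)
        choices = normative.simulate_choices(trace.psi, true.v, rng)
        fit = learner.fit_learner(choices, mixed_session.tone, n_starts=5, seed=0)
        assert fit.mu == pytest.approx(true.mu, abs=0.1)
        assert np.log(fit.phi) == pytest.approx(np.log(true.phi), abs=np.log(2.5))
        assert fit.v == pytest.approx(true.v, abs=0.15)
        assert not fit.weakly_identified

    def test_near_random_choices_flag_weak_identification(self, mixed_session, rng):
        true = learner.LearnerParams(mu=0.5, phi=2.0, K=0.01, v=50.0)
        trace = learner.run(mixed_session.tone, true, n_grid=50)
        choices = normative.simulate_choices(trace.psi, true.v, rng)
        fit = learner.fit_learner(choices, mixed_session.tone, n_starts=4, seed=1)
        # the fit cannot beat chance, however the noise is absorbed
        assert fit.fit_loss / len(mixed_session) == pytest.approx(np.log(2), abs=0.01)
        assert fit.weakly_identified

    def test_fit_is_locally_optimal_for_own_predictions(self, mixed_session, rng):
        true = learner.LearnerParams(mu=0.4, phi=5.0, K=0.01, v=0.5)
        trace = learner.run(mixed_session.tone, true, n_grid=50)
        choices = normative.simulate_choices(trace.psi, true.v, rng)
        fit = learner.fit_learner(choices, mixed_session.tone, n_starts=5, seed=2)
        best = fit.fit_loss
        for mu_pert, phi_pert in [(0.1, 1.0), (-0.1, 1.0), (0.0, 3.0), (0.0, 1 / 3.0)]:
            pert = learner.LearnerParams(
                mu=np.clip(fit.mu + mu_pert, 0.05, 0.95),
                phi=fit.phi * phi_pert,
                K=fit.K,
                v=fit.v,
            )
            tr = learner.run(mixed_session.tone, pert, n_grid=50)
            loss = normative.cross_entropy(
                choices, normative.choice_prob(tr.psi, pert.v)
            )
            assert loss >= best - 1e-6


class TestReferenceTrace:
    def test_reference_is_deterministic(self, mixed_session):
        a = learner.reference_trace(mixed_session.tone[:500])
        b = learner.reference_trace(mixed_session.tone[:500])
        np.testing.assert_array_equal(a.psi, b.psi)

    def test_prediction_accuracy_ordering_across_hazards(self):
        # the wide-prior model predicts far better in the predictable
        # regimes (low/high hazard) than under the intermediate hazard,
        # the most unpredictable condition
        acc = {}
        for h, label in [(0.01, "low"), (0.3, "int"), (0.99, "high")]:
            cfg = TaskConfig(block_schedule=[(h, 2000)], n_trials=2000, seed=10)
            s = generate_session(cfg)
            trace = learner.reference_trace(s.tone, n_grid=50)
            pred = (trace.psi > 0).astype(int)
            acc[label] = np.mean(pred == s.source)
        assert acc["low"] > acc["int"]
        assert acc["high"] > acc["int"]
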