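import numpy as np
import pandas as pd
import pytest

from beliefpupil import pipeline, regression, synth, task
from beliefpupil.learner import LearnerTrace
from beliefpupil.pupil import TrialPupil


def make_trace(belief, surprisal):
    belief = np.asarray(belief, float)
    surprisal = np.asarray(surprisal, float)
    return LearnerTrace(
        psi=belief.copy(),
        L=belief.copy(),
        belief_strength=belief,
        surprisal=surprisal,
        surprisal_conditional=surprisal,
        posterior_mean_h=np.full(len(belief), 0.3),
    )


def make_pupil(baseline, peak):
    n = len(baseline)
    baseline = np.asarray(baseline, float)
    peak = np.asarray(peak, float)
    evoked = peak[:, None] * np.linspace(0, 1, 121)[None, :]
    return TrialPupil(
        baseline=baseline,
        evoked=evoked,
        peak_evoked=peak,
        next_baseline=np.append(baseline[1:], np.nan),
        frac_interpolated=np.zeros(n),
        excluded=np.zeros(n, dtype=bool),
    )


def make_trials(n, rng, rt=None):
    return pd.DataFrame(
        {
            "tone": rng.integers(0, 2, n),
            "choice": rng.integers(0, 2, n),
            "hazard": np.where(np.arange(n) < n // 2, 0.01, 0.99),
            "rt_s": np.full(n, 0.5) if rt is None else rt,
        }
    )


class TestBuildDesign:
    def test_first_trial_dropped_and_nuisance_counts(self, rng):
        n = 60
        trials = make_trials(n, rng)
        trace = make_trace(rng.random(n), rng.random(n))
        pup = make_pupil(rng.random(n), rng.random(n))
        d_base = regression.build_design(trials, trace, pup, "baseline")
        assert len(d_base.y) == n - 1
        assert d_base.nuisance_names == ["prev_evoked_peak"]
        d_ev = regression.build_design(trials, trace, pup, "evoked")
        assert d_ev.nuisance_names == [
            "current_baseline",
            "prev_evoked_peak",
            "prev_baseline",
        ]
        assert d_ev.y.shape == (n - 1, 121)

    def test_lagged_nuisances_pair_correctly_on_hand_fixture(self):
        trials = pd.DataFrame(
            {
                "tone": [0, 1, 1, 0, 1],
                "choice": [0, 0, 1, 1, 0],
                "hazard": [0.3] * 5,
                "rt_s": [0.5] * 5,
            }
        )
        baseline = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        peak = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        design = regression.build_design(
            trials, None, make_pupil(baseline, peak), "evoked",
            regressors=["tone_switch"],
        )
        # trial t carries trial t-1's peak and baseline
        np.testing.assert_array_equal(design.X["prev_evoked_peak"], [1, 2, 3, 4])
        np.testing.assert_array_equal(design.X["prev_baseline"], [10, 20, 30, 40])
        np.testing.assert_array_equal(design.X["current_baseline"], [20, 30, 40, 50])
        np.testing.assert_array_equal(design.X["tone_switch"], [1, 0, 1, 1])

    def test_excluded_trials_are_dropped(self, rng):
        n = 80
        trials = make_trials(n, rng)
        pup = make_pupil(rng.random(n), rng.random(n))
        pup.excluded[10:20] = True
        design = regression.build_design(
            trials, None, pup, "baseline", regressors=["tone_switch"]
        )
        assert len(design.y) == n - 1 - 10

    def test_misaligned_inputs_raise(self, rng):
        trials = make_trials(50, rng)
        with pytest.raises(ValueError, match="misaligned"):
            regression.build_design(
                trials, make_trace(np.zeros(40), np.zeros(40)), None, "log_rt"
            )

    def test_decorrelated_switches_stay_well_conditioned(self, extreme_session, rng):
        # tone switches are stimulus-driven, prediction switches are
        # behavior-driven; on synthetic data they decorrelate and both
        # effects are separately recoverable
        n = len(extreme_session)
        spec = synth.AgentSpec.for_class("bayesian_wide")
        choices, _, _ = synth.simulate_agent(spec, extreme_session, rng, 50)
        trials = pd.DataFrame(
            {
                "tone": extreme_session.tone,
                "choice": choices,
                "hazard": extreme_session.hazard,
                "rt_s": np.full(n, 0.5),
            }
        )
        pup = make_pupil(rng.random(n), rng.random(n))
        design = regression.build_design(
            trials, None, pup, "baseline",
            regressors=["tone_switch", "prediction_switch"],
        )
        X = design.X.to_numpy()
        X = (X - X.mean(0)) / X.std(0)
        cond = np.linalg.cond(np.column_stack([np.ones(len(X)), X]))
        assert cond < 30


class TestFitSubject:
    def test_exact_linear_recovery(self, rng):
        n = 200
        trials = make_trials(n, rng)
        trace = make_trace(rng.random(n), rng.random(n))
        pup = make_pupil(rng.random(n), rng.random(n))
        design = regression.build_design(trials, trace, pup, "baseline")
        design.y = 2.0 * design.X["surprisal"].to_numpy() + 0.5
        betas = regression.fit_subject(design)
        assert betas["surprisal"] == pytest.approx(2.0, abs=1e-10)
        assert betas["belief_strength"] == pytest.approx(0.0, abs=1e-10)

    def test_pure_noise_betas_are_within_sampling_error(self, rng):
        n = 1001
        trials = make_trials(n, rng)
        trace = make_trace(rng.random(n), rng.random(n))
        pup = make_pupil(rng.random(n), rng.random(n))
        design = regression.build_design(trials, trace, pup, "baseline")
        design.y = rng.standard_normal(len(design.y))
        betas = regression.fit_subject(design)
        se = 1.0 / np.sqrt(len(design.y))  # z-scored regressors
        assert np.all(np.abs(betas[["belief_strength", "surprisal"]]) < 3.5 * se)

    def test_collinear_column_dropped_with_warning(self, rng):
        n = 100
        trials = make_trials(n, rng)
        pup = make_pupil(rng.random(n), rng.random(n))
        design = regression.build_design(
            trials, None, pup, "baseline", regressors=["tone_switch"]
        )
        design.X["dup"] = design.X["tone_switch"]
        with pytest.warns(UserWarning, match="collinear"):
            betas = regression.fit_subject(design)
        assert betas.isna().sum() == 1

    def test_too_few_trials_raise(self, rng):
        trials = make_trials(20, rng)
        pup = make_pupil(rng.random(20), rng.random(20))
        design = regression.build_design(
            trials, None, pup, "baseline", regressors=["tone_switch"]
        )
        with pytest.raises(ValueError, match="usable trials"):
            regression.fit_subject(design)

    def test_frisch_waugh_equivalence_on_orthogonalized_design(self, rng):
        # residualizing the target on the nuisances then regressing on
        # the (orthogonalized) effect equals the joint fit coefficient
        n = 400
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = 1.5 * x - 0.7 * z + 0.1 * rng.standard_normal(n)
        X_full = np.column_stack([np.ones(n), x, z])
        joint = np.linalg.lstsq(X_full, y, rcond=None)[0][1]
        Z = np.column_stack([np.ones(n), z])
        res_y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        res_x = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        two_stage = np.linalg.lstsq(res_x[:, None], res_y, rcond=None)[0][0]
        assert two_stage == pytest.approx(joint, abs=1e-10)


class TestGroupInference:
    def test_planted_signs_recovered_with_significance(self, rng):
        n_sub, n_trials = 12, 400
        rows = []
        for _ in range(n_sub):
            trials = make_trials(n_trials, rng)
            belief = rng.random(n_trials)
            surp = rng.random(n_trials)
            trace = make_trace(belief, surp)
            pup = make_pupil(
                5.0 - 0.3 * belief + 0.1 * rng.standard_normal(n_trials),
                rng.random(n_trials),
            )
            design = regression.build_design(trials, trace, pup, "baseline")
            rows.append(regression.fit_subject(design))
        res = regression.group_inference(pd.DataFrame(rows))
        assert res.mean_beta["belief_strength"] < 0
        assert res.p["belief_strength"] < 0.01
        assert res.p["surprisal"] > 0.05

    def test_wilcoxon_variant_agrees_on_signs(self, rng):
        betas = pd.DataFrame({"b": rng.standard_normal(20) + 1.0})
        t_res = regression.group_inference(betas, method="ttest")
        w_res = regression.group_inference(betas, method="wilcoxon")
        assert t_res.p["b"] < 0.01 and w_res.p["b"] < 0.01

    def test_timecourse_fwe_mask_null_and_planted(self, rng):
        n_sub, n_t = 14, 121
        null = rng.standard_normal((n_sub, n_t))
        res = regression.group_inference({"reg": null}, n_perm=300, seed=1)
        assert res.fwe_mask["reg"].sum() == 0
        planted = null + np.where(np.arange(n_t) > 60, 2.0, 0.0)
        res2 = regression.group_inference({"reg": planted}, n_perm=300, seed=1)
        assert res2.fwe_mask["reg"][70:].mean() > 0.9
        assert not res2.fwe_mask["reg"][:50].any()

    def test_too_few_subjects_raise(self):
        with pytest.raises(ValueError, match="at least 5"):
            regression.group_inference(pd.DataFrame({"b": [0.1, 0.2, 0.3]}))


class TestComplexityModulation:
    def test_permuted_labels_give_null_correlation(self, rng):
        betas = rng.standard_normal(40)
        comp = rng.permutation(np.linspace(0, 1, 40))
        out = regression.complexity_modulation(betas, comp)
        assert abs(out["rho"]) < 0.4
        assert out["n"] == 40

    def test_graded_relation_is_detected(self):
        comp = np.linspace(0.1, 1.0, 30)
        betas = -0.5 * comp
        out = regression.complexity_modulation(betas, comp)
        assert out["rho"] == pytest.approx(-1.0, abs=1e-12)
        assert out["p"] < 1e-6

    def test_small_cohort_warns(self, rng):
        with pytest.warns(UserWarning, match="unstable"):
            regression.complexity_modulation(rng.random(5), rng.random(5))


class TestRTModels:
    def test_planted_rt_couplings_recovered(self, rng):
        n = 1500
        trials = make_trials(n, rng)
        belief = rng.random(n) * 3
        surp = rng.random(n) * 2
        trace = make_trace(belief, surp)
        prev_surp_z = regression._zscore_by_group(surp, trials["hazard"].to_numpy())
        log_rt = -0.6 - 0.2 * regression._zscore_by_group(
            belief, trials["hazard"].to_numpy()
        )
        log_rt[1:] += 0.1 * prev_surp_z[:-1]
        trials["rt_s"] = np.exp(log_rt + 0.05 * rng.standard_normal(n))
        betas = regression.rt_models(trials, trace)
        assert betas["belief_strength"] == pytest.approx(-0.2, abs=0.02)
        assert betas["prev_surprisal"] == pytest.approx(0.1, abs=0.02)

    def test_lag_pairing_on_hand_fixture(self):
        # next-trial RT must see the previous trial's surprisal
        trials = pd.DataFrame(
            {
                "tone": [0, 1, 0, 1, 0, 1] * 10,
                "choice": [0, 1, 1, 0, 0, 1] * 10,
                "hazard": [0.3] * 60,
                "rt_s": [0.5] * 60,
            }
        )
        surp = np.arange(60, dtype=float)
        trace = make_trace(np.zeros(60), surp)
        design = regression.build_design(
            trials, trace, None, "log_rt", regressors=["prev_surprisal"]
        )
        surp_z = regression._zscore_by_group(surp, trials["hazard"].to_numpy())
        np.testing.assert_allclose(design.X["prev_surprisal"], surp_z[:-1])

    def test_constant_rts_give_zero_betas(self, rng):
        n = 400
        trials = make_trials(n, rng)
        trace = make_trace(rng.random(n), rng.random(n))
        betas = regression.rt_models(trials, trace)
        np.testing.assert_allclose(betas, 0.0, atol=1e-10)

    def test_nonpositive_rts_dropped_with_warning(self, rng):
        n = 200
        trials = make_trials(n, rng)
        trials.loc[5:9, "rt_s"] = 0.0
        trace = make_trace(rng.random(n), rng.random(n))
        with pytest.warns(UserWarning, match="nonpositive"):
            betas = regression.rt_models(trials, trace)
        assert betas.notna().all()
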