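"""Inference pipeline: survival, ε, mixture MLE, decay profiles, kinetic fits."""

import numpy as np
import pytest

import lifediff as ld
from lifediff import analysis as an
from lifediff.models import KineticModel, displacement_scale2

FRAME_DT = 1.0 / 30.0


class TestDissociationCurve:
    def test_no_dissociation_raises(self):
        m = KineticModel(D=[0.01], lam=[0.0], q=[1.0], eps=0.04)
        ens = ld.simulate_ensemble(m, 20, seed=0, horizon=2.0)
        with pytest.raises(ValueError):
            ld.dissociation_curve(ens)

    def test_exponential_log_slope(self, demo_1state):
        ens = ld.simulate_ensemble(demo_1state, 3000, seed=1)
        curve = ld.dissociation_curve(ens)
        rate, se = curve.decay_rate()
        assert rate == pytest.approx(1.0, abs=max(4 * se, 0.05))
        assert curve.at(0.0) == pytest.approx(1.0)

    def test_survival_matches_theory_on_grid(self, switching_ensemble,
                                             demo_switching):
        curve = ld.dissociation_curve(switching_ensemble)
        t = np.array([0.5, 1.0, 2.0, 5.0])
        R = ld.residence_probability(demo_switching, t)
        se = np.sqrt(R * (1 - R) / len(switching_ensemble))
        assert np.all(np.abs(curve.at(t) - R) < 4 * se)

    def test_photobleaching_only_decay_not_flagged_as_dissociation(self):
        # immobilized molecules disappear at lam_b alone; the pipeline must
        # not report membrane dissociation
        m = KineticModel(D=[0.01], lam=[0.0], q=[1.0], lam_b=0.1, eps=0.04)
        ens = ld.simulate_ensemble(m, 1500, seed=2, include_photobleach=True)
        curve = ld.dissociation_curve(ens)
        rate, se = curve.decay_rate()
        assert rate - 1.96 * se <= 0.1
        assert rate == pytest.approx(0.1, rel=0.25)


class TestEpsilonEstimate:
    def test_immobile_tracks_recover_eps(self):
        m = KineticModel(D=[0.0], lam=[0.3], q=[1.0], eps=0.040)
        ens = ld.simulate_ensemble(m, 500, seed=3, horizon=10.0)
        msd = ld.estimate_epsilon(ens)
        assert 0.036 <= msd.eps <= 0.044

    def test_zero_error_zero_diffusion(self):
        m = KineticModel(D=[0.0], lam=[0.3], q=[1.0], eps=0.0)
        ens = ld.simulate_ensemble(m, 50, seed=4, horizon=5.0)
        msd = ld.estimate_epsilon(ens)
        assert msd.eps == 0.0 and np.all(msd.msd == 0.0)

    def test_slope_recovers_diffusion_coefficient(self):
        m = KineticModel(D=[0.08], lam=[0.2], q=[1.0], eps=0.04)
        ens = ld.simulate_ensemble(m, 500, seed=5, horizon=20.0)
        msd = ld.estimate_epsilon(ens)
        assert msd.D_star == pytest.approx(0.08, rel=0.10)
        assert msd.eps == pytest.approx(0.04, rel=0.15)


class TestMixtureMLE:
    def test_em_matches_grid_search_oracle(self):
        """On a small sample, EM must reach the dense-grid likelihood optimum."""
        rng = np.random.default_rng(11)
        eps, dt = 0.03, FRAME_DT
        s2 = displacement_scale2(np.array([0.01, 0.2]), eps, dt)
        comp = rng.random(200) < 0.4
        r = rng.rayleigh(np.sqrt(2 * np.where(comp, s2[0], s2[1])))

        def loglik(D1, D2, p1):
            sig = displacement_scale2(np.array([D1, D2]), eps, dt)
            f = (np.array([p1, 1 - p1])[None, :] * r[:, None]
                 / (2 * sig) * np.exp(-r[:, None] ** 2 / (4 * sig)))
            return np.log(f.sum(axis=1)).sum()

        D1g = np.linspace(0.002, 0.05, 25)
        D2g = np.linspace(0.05, 0.5, 24)
        p1g = np.linspace(0.05, 0.95, 19)
        best, arg = -np.inf, None
        for a in D1g:
            for b in D2g:
                for c in p1g:
                    ll = loglik(a, b, c)
                    if ll > best:
                        best, arg = ll, (a, b, c)
        fit = ld.fit_displacement_mixture(r, 2, eps, dt)
        assert fit.log_likelihood >= best - 1e-6
        assert abs(fit.D[0] - arg[0]) <= np.diff(D1g)[0]
        assert abs(fit.D[1] - arg[1]) <= np.diff(D2g)[0]
        assert abs(fit.p[0] - arg[2]) <= np.diff(p1g)[0]

    def test_single_state_data_selects_one_state(self, demo_1state):
        ens = ld.simulate_ensemble(demo_1state, 800, seed=6)
        fits, chosen = ld.select_state_number(ens.displacements(), 0.04,
                                              FRAME_DT, n_max=3)
        assert chosen == 1

    def test_aic_formula(self, switching_mixture_fit):
        f = switching_mixture_fit
        assert f.aic == pytest.approx(-2 * f.log_likelihood + 2 * (2 * 2 - 1))
        assert np.all(np.diff(f.D) > 0)
        assert f.p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_components_flagged_by_infinite_ci(self):
        rng = np.random.default_rng(12)
        s2 = displacement_scale2(0.05, 0.0, FRAME_DT)
        r = rng.rayleigh(np.sqrt(2 * s2), size=400)
        fit = ld.fit_displacement_mixture(r, 2, 0.0, FRAME_DT,
                                          D_init=[0.05, 0.05], n_restarts=1,
                                          compute_ci=True)
        width = fit.D_ci[:, 1] - fit.D_ci[:, 0]
        assert np.any(~np.isfinite(width)) or np.any(width > 10 * fit.D.max())

    def test_all_zero_displacements_rejected(self):
        with pytest.raises(ValueError):
            ld.fit_displacement_mixture(np.zeros(100), 1, 0.04, FRAME_DT)


class TestDecayProfiles:
    def test_profiles_sum_to_survival_by_construction(self, switching_profiles):
        assert np.allclose(switching_profiles.Q_obs.sum(axis=1),
                           switching_profiles.R_obs, atol=1e-12)
        assert np.allclose(switching_profiles.p_t.sum(axis=1), 1.0, atol=1e-9)

    def test_first_window_fractions_near_initial_probabilities(
            self, switching_profiles, demo_switching):
        se = switching_profiles.se_p[0]
        assert np.all(np.abs(switching_profiles.p_t[0] - demo_switching.q)
                      < 4 * se + 0.02)

    def test_slow_state_fraction_grows_without_transitions(self, demo_static):
        ens = ld.simulate_ensemble(demo_static, 1500, seed=7)
        prof = ld.windowed_fractions(ens, demo_static.D, 0.04)
        late = prof.t > 2.0
        assert prof.p_t[late, 0].mean() > 0.85 > prof.p_t[0, 0] + 0.5


class TestTransitionDetection:
    def test_static_model_shows_no_transitions(self, demo_static):
        ens = ld.simulate_ensemble(demo_static, 1000, seed=0)
        fit = ld.fit_displacement_mixture(ens.displacements(), 2, 0.04, FRAME_DT)
        prof = ld.windowed_fractions(ens, fit.D, 0.04)
        assert ld.detect_transitions(prof).present is False

    def test_switching_model_shows_transitions(self, switching_profiles):
        assert ld.detect_transitions(switching_profiles).present is True

    def test_three_state_slopes_converge_after_transient(self, pten3):
        ens = ld.simulate_ensemble(pten3, 3000, seed=0)
        fit = ld.fit_displacement_mixture(ens.displacements(), 3, pten3.eps,
                                          FRAME_DT)
        prof = ld.windowed_fractions(ens, fit.D, pten3.eps)
        tt = ld.detect_transitions(prof)
        assert tt.present is True
        assert tt.t_late <= 1.0  # common decay reached within ~0.5-1 s

    def test_insufficient_late_data_is_indeterminate(self, demo_switching):
        ens = ld.simulate_ensemble(demo_switching, 60, seed=8, horizon=1.0)
        fit = ld.fit_displacement_mixture(ens.displacements(), 2, 0.04, FRAME_DT)
        prof = ld.windowed_fractions(ens, fit.D, 0.04, min_count=20)
        assert ld.detect_transitions(prof).present is None


class TestKineticFit:
    def test_noise_free_profiles_recover_parameters(self, demo_switching):
        t = np.arange(0, 10, FRAME_DT)
        Q = ld.subpopulation_probabilities(demo_switching, t)
        R = Q.sum(axis=1)
        prof = an.DecayProfiles(t=t, tau=FRAME_DT, p_t=Q / R[:, None],
                                R_obs=R, Q_obs=Q,
                                counts=np.full(t.size, 1000),
                                D=demo_switching.D, eps=demo_switching.eps,
                                frame_dt=FRAME_DT, n_tracks=10**9,
                                se_p=np.full((t.size, 2), 1e-6))
        kin = ld.fit_state_kinetics(prof, topology="chain", lam_b=0.0)
        assert np.allclose(kin.lam_apparent, [0.10, 1.00], rtol=1e-4)
        assert kin.k[0, 1] == pytest.approx(0.10, rel=1e-4)
        assert kin.k[1, 0] == pytest.approx(0.50, rel=1e-4)
        assert kin.q[0] == pytest.approx(0.20, rel=1e-4)

    def test_static_data_with_transitions_allowed_gives_near_zero_k(
            self, static_ensemble, demo_static):
        fit = ld.fit_displacement_mixture(static_ensemble.displacements(), 2,
                                          0.04, FRAME_DT)
        prof = ld.windowed_fractions(static_ensemble, fit.D, 0.04)
        kin = ld.fit_state_kinetics(prof, topology="chain", lam_b=0.0)
        assert kin.k[0, 1] < 0.1 and kin.k[1, 0] < 0.1
        assert np.allclose(kin.lam_apparent, demo_static.lam, rtol=0.25)

    def test_not_determined_flag_set_when_rate_below_bleaching(
            self, switching_profiles):
        kin = ld.fit_state_kinetics(switching_profiles, topology="chain",
                                    lam_b=0.3)
        assert np.array_equal(kin.not_determined, kin.lam_apparent <= 0.3)
        assert kin.not_determined[0]


class TestAutocorrelation:
    def test_single_state_displacements_uncorrelated(self):
        m = KineticModel(D=[0.1], lam=[0.0], q=[1.0], eps=0.0)
        ens = ld.simulate_ensemble(m, 10, seed=9, horizon=60.0)
        fit = ld.displacement_autocorrelation(ens, max_lag=15)
        assert fit.acf[0] == pytest.approx(1.0)
        assert np.all(np.abs(fit.acf[1:]) < 0.05)

    def test_switching_rate_recovered_from_acf_decay(self):
        # mobility alternation relaxes at k12 + k21 = 2.0 1/s
        m = KineticModel(D=[0.01, 0.30], lam=[0.0, 0.0],
                         k={(0, 1): 1.0, (1, 0): 1.0}, q=[0.5, 0.5], eps=0.0)
        ens = ld.simulate_ensemble(m, 10, seed=10, horizon=60.0)
        fit = ld.displacement_autocorrelation(ens, max_lag=30)
        assert fit.K == pytest.approx(2.0, rel=0.20)

    def test_short_tracks_rejected(self, demo_1state):
        ens = ld.simulate_ensemble(demo_1state, 5, seed=11, horizon=0.2)
        with pytest.raises(ValueError):
            ld.displacement_autocorrelation(ens, max_lag=30)


class TestConsistencyCheck:
    def test_wrong_model_rejected(self, switching_ensemble, demo_switching):
        frozen = demo_switching.with_(D=np.array([1e-4, 1e-3]))
        recs = ld.consistency_check(switching_ensemble, frozen, [1.0])
        assert recs[0]["chi2"] > 100 and recs[0]["p_value"] < 1e-6

    def test_true_model_not_rejected(self, switching_ensemble, demo_switching):
        recs = ld.consistency_check(switching_ensemble, demo_switching,
                                    [1.0, 3.0])
        for rec in recs:
            assert rec["p_value"] > 1e-4


class TestFullPipeline:
    def test_single_state_end_to_end(self, demo_1state):
        ens = ld.simulate_ensemble(demo_1state, 1000, seed=12)
        rep = ld.run_full_analysis(ens, lam_b=0.0, eps=0.04,
                                   consistency_times=(0.5, 1.0))
        assert rep.chosen_n == 1
        assert rep.membrane_dissociation
        assert rep.kinetic_fit.lam_apparent[0] == pytest.approx(1.0, rel=0.10)

    def test_empty_ensemble_rejected(self):
        ens = ld.TrajectoryEnsemble(trajectories=[], frame_dt=FRAME_DT)
        with pytest.raises(ValueError):
            ld.run_full_analysis(ens)

    def test_report_serializes(self, demo_1state, tmp_path):
        import json

        ens = ld.simulate_ensemble(demo_1state, 400, seed=13)
        rep = ld.run_full_analysis(ens, lam_b=0.0, eps=0.04,
                                   consistency_times=(0.5,), n_max=2)
        out = tmp_path / "report.json"
        ld.io.write_report(rep, out)
        data = json.loads(out.read_text())
        assert data["schema_version"] == 1
        assert data["state_number"]["chosen_n"] == 1
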