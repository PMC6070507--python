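"""Growth equations, LV dynamics, fitting and model comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cocom.growth import (
    GrowthParams,
    LVParams,
    Trajectory,
    classify_interaction,
    compare_growth_models,
    decompose_lv,
    eval_growth,
    f_test_nested,
    fit_growth,
    fit_lv,
    gaussian_loglik,
    partition_phases,
    plasticity_curve,
    select_by_aic,
    solve_lv,
    STRATEGY_MATRIX,
)

class TestEvalGrowth:
    def test_logistic_at_lag_time(self):
        p = GrowthParams("logistic", A=10.0, r=2.0, lam=1.5)
        assert eval_growth(p, 1.5) == pytest.approx(10.0 / (1.0 + math.e**2))

    def test_gompertz_at_lag_time(self):
        p = GrowthParams("gompertz", A=7.0, r=1.0, lam=2.0)
        assert eval_growth(p, 2.0) == pytest.approx(7.0 * math.exp(-math.e))

    def test_richards_v1_equals_logistic(self):
        grid = np.linspace(0.0, 30.0, 121)
        log = eval_growth(GrowthParams("logistic", A=5.0, r=0.8, lam=2.0), grid)
        ric = eval_growth(GrowthParams("richards", A=5.0, r=0.8, lam=2.0, v=1.0), grid)
        np.testing.assert_allclose(ric, log, rtol=1e-12, atol=1e-12)

    def test_approaches_asymptote(self):
        for model, v in (("gompertz", None), ("logistic", None), ("richards", 2.5)):
            p = GrowthParams(model, A=3.0, r=1.0, lam=0.5, v=v)
            assert eval_growth(p, 500.0) == pytest.approx(3.0, rel=1e-6)

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            GrowthParams("verhulst", A=1, r=1, lam=0)
        with pytest.raises(ValueError):
            GrowthParams("logistic", A=-1, r=1, lam=0)
        with pytest.raises(ValueError):
            GrowthParams("richards", A=1, r=1, lam=0)  # missing v
        with pytest.raises(ValueError):
            eval_growth(GrowthParams("logistic", A=1, r=1, lam=0), -1.0)


class TestSolveLV:
    def test_decoupled_matches_logistic_closed_form(self, times):
        p = LVParams(r_e=0.8, K_e=1e9, alpha_es=0.0, r_s=0.6, K_s=5e8, alpha_se=0.0)
        te, ts = solve_lv(p, 5e3, 7e3, times, step=0.01)

        def closed(r, K, n0):
            return K * n0 * np.exp(r * times) / (K + n0 * (np.exp(r * times) - 1.0))

        np.testing.assert_allclose(te.values, closed(0.8, 1e9, 5e3),
                                   rtol=1e-6)
        np.testing.assert_allclose(ts.values, closed(0.6, 5e8, 7e3),
                                   rtol=1e-6)

    def test_zero_initial_state_is_absorbing(self, lv_antagonistic, times):
        te, ts = solve_lv(lv_antagonistic, 0.0, 5e3, times)
        assert np.all(te.values == 0.0)
        assert ts.values[-1] > 1e8  # partner grows logistically

    def test_symmetric_params_give_identical_trajectories(self, times):
        p = LVParams(r_e=0.7, K_e=6e8, alpha_es=0.2, r_s=0.7, K_s=6e8, alpha_se=0.2)
        te, ts = solve_lv(p, 4e3, 4e3, times)
        np.testing.assert_allclose(te.values, ts.values, rtol=1e-12)

    def test_deterministic(self, lv_antagonistic, times):
        a = solve_lv(lv_antagonistic, 5e3, 5e3, times)[0].values
        b = solve_lv(lv_antagonistic, 5e3, 5e3, times)[0].values
        assert np.array_equal(a, b)


class TestDecomposeLV:
    def test_conservation(self, lv_antagonistic, solved_pair):
        te, ts = solved_pair
        de, ds = decompose_lv(lv_antagonistic, te, ts)
        for d in (de, ds):
            err = np.max(np.abs(d.overall.values - d.independent.values - d.interactive))
            assert err < 1e-6 * d.overall.values.max()

    def test_mutual_inhibition_gives_negative_interactive_curves(
            self, lv_antagonistic, solved_pair):
        te, ts = solved_pair
        de, ds = decompose_lv(lv_antagonistic, te, ts)
        assert np.all(de.interactive <= 1e-9)
        assert np.all(ds.interactive <= 1e-9)

    def test_zero_alpha_zero_interactive(self, times):
        p = LVParams(r_e=0.8, K_e=1e9, alpha_es=0.0, r_s=0.6, K_s=5e8, alpha_se=0.5)
        te, ts = solve_lv(p, 5e3, 5e3, times)
        de, _ = decompose_lv(p, te, ts)
        assert np.max(np.abs(de.interactive)) < 1e-6 * te.values.max()

    def test_mismatched_params_rejected(self, lv_antagonistic, solved_pair, times):
        te, ts = solved_pair
        other = LVParams(r_e=2.0, K_e=1e8, alpha_es=-1.0, r_s=0.1, K_s=1e9,
                         alpha_se=2.0)
        with pytest.raises(ValueError, match="do not solve"):
            decompose_lv(other, te, ts)


class TestFitGrowth:
    @pytest.mark.parametrize("model,extra", [("gompertz", {}), ("logistic", {}),
                                             ("richards", {"v": 1.7})])
    def test_noiseless_self_recovery(self, model, extra, times):
        true = GrowthParams(model, A=1e9, r=1.5e8, lam=3.0, **extra)
        traj = Trajectory(times, eval_growth(true, times))
        est, rss, n = fit_growth(traj, model)
        assert n == len(times)
        np.testing.assert_allclose(est.as_array(), true.as_array(), rtol=1e-4)

    def test_constant_trajectory_rejected(self, times):
        with pytest.raises(ValueError, match="constant"):
            fit_growth(Trajectory(times, np.full(len(times), 2.0)), "logistic")

    def test_richards_on_logistic_data_finds_v_near_one(self, times):
        true = GrowthParams("logistic", A=1e9, r=1.5e8, lam=3.0)
        traj = Trajectory(times, eval_growth(true, times))
        est, _, _ = fit_growth(traj, "richards")
        assert est.v == pytest.approx(1.0, abs=1e-3)


class TestFitLV:
    def test_noiseless_recovery(self, lv_antagonistic, solved_pair):
        te, ts = solved_pair
        est, rss, ll = fit_lv(te, ts)
        np.testing.assert_allclose(est.as_array(), lv_antagonistic.as_array(),
                                   rtol=1e-3)
        assert np.isfinite(ll)

    def test_null_interaction_recovered_as_near_zero(self, times):
        p = LVParams(r_e=1.0, K_e=8e8, alpha_es=0.0, r_s=0.8, K_s=5e8, alpha_se=0.0)
        te, ts = solve_lv(p, 5e3, 5e3, times)
        est, _, _ = fit_lv(te, ts)
        assert abs(est.alpha_es) < 0.05
        assert abs(est.alpha_se) < 0.05

    def test_residuals_uncorrelated_with_fitted(self, lv_antagonistic, times):
        rng = np.random.default_rng(5)
        te, ts = solve_lv(lv_antagonistic, 5e3, 5e3, times)
        noisy_e = Trajectory(times, np.maximum(te.values * (1 + rng.normal(0, 0.02, len(times))), 0))
        noisy_s = Trajectory(times, np.maximum(ts.values * (1 + rng.normal(0, 0.02, len(times))), 0))
        est, _, _ = fit_lv(noisy_e, noisy_s)
        fe, fs = solve_lv(est, noisy_e.values[0], noisy_s.values[0], times)
        fitted = np.concatenate([fe.values, fs.values])
        resid = np.concatenate([noisy_e.values, noisy_s.values]) - fitted
        # scale residuals per species before pooling
        sc = np.concatenate([np.full(len(times), te.values.max()),
                             np.full(len(times), ts.values.max())])
        rho = np.corrcoef(fitted / sc, resid / sc)[0, 1]
        assert abs(rho) < 0.35  # no systematic trend


class TestModelComparison:
    def test_equal_rss_gives_f_zero_p_one(self, times):
        p3 = GrowthParams("logistic", A=1.0, r=1.0, lam=0.0)
        p4 = GrowthParams("richards", A=1.0, r=1.0, lam=0.0, v=1.0)
        F, p = f_test_nested((p3, 2.5, 16), (p4, 2.5, 16))
        assert F == 0.0
        assert p == pytest.approx(1.0)

    def test_richards_data_rejects_logistic(self, times):
        rng = np.random.default_rng(11)
        true = GrowthParams("richards", A=1e9, r=1.5e8, lam=3.0, v=3.0)
        mean = eval_growth(true, times)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            noisy = np.maximum(mean + rng.normal(0, 0.01 * 1e9, len(times)), 0.0)
            _, _, (F, p) = compare_growth_models(Trajectory(times, noisy), "logistic")
            hits += p < 0.05
        assert hits >= 0.9 * n_rep

    def test_logistic_data_keeps_logistic(self, times):
        rng = np.random.default_rng(12)
        true = GrowthParams("logistic", A=1e9, r=1.5e8, lam=3.0)
        mean = eval_growth(true, times)
        keep = 0
        n_rep = 100
        for _ in range(n_rep):
            noisy = np.maximum(mean + rng.normal(0, 0.01 * 1e9, len(times)), 0.0)
            _, _, (F, p) = compare_growth_models(Trajectory(times, noisy), "logistic")
            keep += p > 0.05
        assert keep >= 0.9 * n_rep

    def test_aic_single_candidate(self):
        assert select_by_aic([("only", -10.0, 3)])[0][0] == "only"

    def test_aic_tie_prefers_fewer_params(self):
        ranking = select_by_aic([("big", -5.0, 4), ("small", -6.0, 2)])
        assert ranking[0][0] == "small"  # same AIC = 2*4+10 = 2*2+12

    def test_aic_empty_rejected(self):
        with pytest.raises(ValueError):
            select_by_aic([])

    def test_lv_beats_single_species_sigmoids_on_co_culture(
            self, lv_antagonistic, solved_pair, times):
        te, ts = solved_pair
        lv_fit, lv_rss, lv_ll = fit_lv(te, ts)
        cand = [("LV", lv_ll, 6)]
        for model in ("gompertz", "logistic", "richards"):
            ll = 0.0
            k = 0
            for traj in (te, ts):
                p, rss, n = fit_growth(traj, model)
                ll += gaussian_loglik(rss, n)
                k += p.n_params
            cand.append((model, ll, k))
        assert select_by_aic(cand)[0][0] == "LV"


class TestPhasesAndInteraction:
    def test_tangent_line_boundaries(self):
        p = GrowthParams("logistic", A=10.0, r=2.0, lam=1.0)
        assert partition_phases(p) == (1.0, 6.0)

    def test_zero_lag_empty_lag_phase(self):
        p = GrowthParams("logistic", A=10.0, r=2.0, lam=0.0)
        t_lag, t_exp = partition_phases(p)
        assert t_lag == 0.0

    @given(A=st.floats(0.1, 1e6), r=st.floats(1e-3, 1e3), lam=st.floats(0, 20))
    @settings(max_examples=100, deadline=None)
    def test_boundaries_ordered_and_clipped(self, A, r, lam):
        p = GrowthParams("logistic", A=A, r=r, lam=lam)
        t_lag, t_exp = partition_phases(p, window=(0.0, 36.0))
        assert 0.0 <= t_lag <= t_exp <= 36.0

    @pytest.mark.parametrize("se,ss,label", sorted(STRATEGY_MATRIX.items()) and [
        (-1, -1, "antagonism"), (0, 0, "independence"), (1, 0, "commensalism"),
        (1, 1, "mutualism"), (-1, 0, "amensalism"), (1, -1, "parasitism"),
        (0, 1, "commensalism"), (0, -1, "amensalism"), (-1, 1, "parasitism")])
    def test_strategy_matrix_cells(self, se, ss, label, times):
        # build synthetic decompositions with prescribed interactive signs
        from cocom.growth import GrowthDecomposition

        base = Trajectory(times, np.linspace(1.0, 100.0, len(times)))

        def decomp(sign):
            inter = sign * np.linspace(0.0, 50.0, len(times))
            indep = Trajectory(times, np.maximum(base.values - inter, 0.0))
            return GrowthDecomposition(overall=base, independent=indep,
                                       interactive=inter)

        it = classify_interaction(decomp(se), decomp(ss), tol=1.0)
        assert it.label == label
        assert (it.sign_e, it.sign_s) == (se, ss)

    def test_interaction_classification_on_solved_system(
            self, lv_antagonistic, solved_pair):
        de, ds = decompose_lv(lv_antagonistic, *solved_pair)
        assert classify_interaction(de, ds).label == "antagonism"


class TestPlasticity:
    def test_identical_cultures_zero_curve(self, solved_pair):
        te, _ = solved_pair
        diff = plasticity_curve(te, te)
        assert np.all(diff.values == 0.0)

    def test_suppressed_co_culture_negative_curve(self, times):
        mono = Trajectory(times, np.linspace(10, 1000, len(times)))
        co = Trajectory(times, np.linspace(5, 500, len(times)))
        diff = plasticity_curve(mono, co)
        assert np.all(diff.values[1:] < 0)

    def test_mean_plasticity_equals_plasticity_of_means(self, times):
        rng = np.random.default_rng(3)
        monos = [Trajectory(times, rng.uniform(1, 10, len(times)).cumsum())
                 for _ in range(5)]
        cos = [Trajectory(times, rng.uniform(1, 10, len(times)).cumsum())
               for _ in range(5)]
        mean_of_curves = np.mean([plasticity_curve(m, c).values
                                  for m, c in zip(monos, cos)], axis=0)
        mono_mean = Trajectory(times, np.mean([m.values for m in monos], axis=0))
        co_mean = Trajectory(times, np.mean([c.values for c in cos], axis=0))
        np.testing.assert_allclose(mean_of_curves,
                                   plasticity_curve(mono_mean, co_mean).values,
                                   rtol=1e-12)

    def test_disjoint_ranges_rejected(self, times):
        mono = Trajectory(times, np.ones(len(times)))
        co = Trajectory(times[:4] + 100.0, np.ones(4))
        with pytest.raises(ValueError):
            plasticity_curve(mono, co)
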