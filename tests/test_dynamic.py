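"""Dynamic mapping: functional-mapping and systems-mapping scans, permutation
thresholds, effect tests and curve contrasts."""

import numpy as np
import pytest
from scipy import stats

from cocom import dynamic_mapping as dm
from cocom.covariance import build_sigma
from cocom.quantgen import GeneticEffects
from cocom.simulate import SimScenario, simulate_dataset
from cocom.static_mapping import GenotypePanel, em_bivariate_mixture, MixtureWeights

from conftest import pair_panels


@pytest.fixture(scope="module")
def null_mono_scan():
    sc = SimScenario(treatment="mono", h2=0.0, n_markers_a=60, n_markers_b=4,
                     seed=21)
    ds = simulate_dataset(sc)
    pa, _ = pair_panels(ds)
    res = dm.functional_mapping_scan(pa, ds.abundance_matrix("a", "mono"), ds.times)
    return sc, ds, res


class TestFunctionalMapping:
    def test_null_lrt_mean_near_df(self, null_mono_scan):
        # H1 adds one 4-parameter Richards curve: df = 4
        _, _, res = null_mono_scan
        mean_lrt = np.nanmean(res.lrt)
        assert 2.5 < mean_lrt < 6.0

    def test_identical_genotype_curves_zero_noise_lrt_zero(self, times):
        # every strain follows exactly the same curve: the genotype groups
        # share their mean trajectory, so the LRT must vanish
        from cocom.growth import GrowthParams, eval_growth
        import pandas as pd

        rng = np.random.default_rng(5)
        n = 45
        curve = eval_growth(GrowthParams("richards", A=5.3, r=0.55, lam=1.0, v=1.2),
                            times)
        y = 5e3 * 10.0 ** np.tile(curve, (n, 1))
        calls = rng.integers(0, 2, (n, 10)).astype(np.int8)
        panel = GenotypePanel(
            pd.DataFrame({"marker_id": [f"M{j}" for j in range(10)],
                          "pos": np.arange(1, 11)}),
            calls, [f"S{i}" for i in range(n)])
        res = dm.functional_mapping_scan(panel, y, times)
        assert np.nanmax(np.abs(res.lrt)) < 1e-3

    def test_planted_marker_top_ranked(self):
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            sc = SimScenario(treatment="mono", h2=0.25, n_pairs=100,
                             n_markers_a=40, n_markers_b=4, causal_a=7,
                             seed=100 + rep)
            ds = simulate_dataset(sc)
            pa, _ = pair_panels(ds)
            res = dm.functional_mapping_scan(pa, ds.abundance_matrix("a", "mono"),
                                             ds.times)
            hits += int(np.nanargmax(res.lrt)) == 7
        assert hits >= 0.8 * n_rep
        # genotype-specific fitted curves at the causal marker separate in A
        gp = res.growth_params(7)
        assert set(gp) == {0, 1}
        assert abs(gp[1].A - gp[0].A) > 0.05


class TestSystemsMapping:
    def test_t1_reduces_to_static_closed_form(self):
        """With a single time point and one-hot weights the systems-mapping ML
        mean estimates equal the static bivariate mixture's group means."""
        rng = np.random.default_rng(8)
        n = 60
        ga, gb = rng.integers(0, 2, n), rng.integers(0, 2, n)
        # positive abundances around 1e6 with combo-dependent shifts
        combo = 2 * ga + gb
        log_y_a = 6.0 + 0.3 * (combo == 3) + rng.normal(0, 0.2, n)
        log_y_b = 5.5 - 0.2 * (combo == 0) + rng.normal(0, 0.2, n)
        times = np.array([4.0])
        fit = dm.systems_mapping_fit(ga, gb, 10.0**log_y_a[:, None],
                                     10.0**log_y_b[:, None], times)
        em = em_bivariate_mixture(log_y_a, log_y_b, MixtureWeights.one_hot(ga, gb))
        # em combo order AB, Ab, aB, ab
        for k, combo_name in enumerate(("AB", "Ab", "aB", "ab")):
            mu = fit.mean_curves[combo_name]
            np.testing.assert_allclose(mu, em["means"][k], atol=2e-3)
        cov = build_sigma(fit.cov, times)
        assert cov[0, 0] == pytest.approx(em["sigma2_a"], rel=0.05)
        assert cov[1, 1] == pytest.approx(em["sigma2_b"], rel=0.05)
        assert cov[0, 1] == pytest.approx(em["rho"] * np.sqrt(em["sigma2_a"] * em["sigma2_b"]),
                                          abs=0.02)

    def test_loglik_ascends_with_one_hot_weights(self, causal_co_dataset):
        sc, ds = causal_co_dataset
        ga = ds.genotype_rows("a")[:, sc.causal_a]
        gb = ds.genotype_rows("b")[:, sc.causal_b]
        logliks = []
        for max_outer in (3, 6, 12):
            fit = dm.systems_mapping_fit(ga, gb, ds.abundance_matrix("a", "co"),
                                         ds.abundance_matrix("b", "co"), ds.times,
                                         max_outer=max_outer, tol=0.0)
            logliks.append(fit.loglik)
        assert logliks[1] >= logliks[0] - 1e-6 * abs(logliks[0])
        assert logliks[2] >= logliks[1] - 1e-6 * abs(logliks[1])

    def test_fit_carries_consistent_effect_curves(self, causal_co_dataset):
        from cocom.quantgen import ComboValues, decompose_effects

        sc, ds = causal_co_dataset
        ga = ds.genotype_rows("a")[:, sc.causal_a]
        gb = ds.genotype_rows("b")[:, sc.causal_b]
        fit = dm.systems_mapping_fit(ga, gb, ds.abundance_matrix("a", "co"),
                                     ds.abundance_matrix("b", "co"), ds.times)
        T = len(ds.times)
        combos = ComboValues(
            species_a=np.stack([fit.mean_curves[c][:T] for c in ("AB", "Ab", "aB", "ab")]),
            species_b=np.stack([fit.mean_curves[c][T:] for c in ("AB", "Ab", "aB", "ab")]))
        ref = decompose_effects(combos)
        np.testing.assert_allclose(fit.effects.direct_a, ref.direct_a, rtol=1e-10)
        np.testing.assert_allclose(fit.effects.epi_b, ref.epi_b, rtol=1e-10)


class TestCocomScan:
    def test_causal_pair_attains_max_lrt(self, causal_co_dataset):
        sc, ds = causal_co_dataset
        pa, pb = pair_panels(ds)
        res = dm.cocom_scan(pa, pb, ds.abundance_matrix("a", "co"),
                            ds.abundance_matrix("b", "co"), ds.times)
        assert np.unravel_index(np.nanargmax(res.lrt), res.lrt.shape) == (3, 3)

    def test_scan_symmetric_under_joint_allele_relabeling(self, null_co_dataset):
        sc, ds = null_co_dataset
        pa, pb = pair_panels(ds)
        ya = ds.abundance_matrix("a", "co")
        yb = ds.abundance_matrix("b", "co")
        res1 = dm.cocom_scan(pa, pb, ya, yb, ds.times)
        pa2 = GenotypePanel(pa.markers, 1 - pa.calls, pa.strains)
        pb2 = GenotypePanel(pb.markers, 1 - pb.calls, pb.strains)
        res2 = dm.cocom_scan(pa2, pb2, ya, yb, ds.times)
        np.testing.assert_allclose(res1.lrt, res2.lrt, rtol=1e-7, atol=1e-7)


class TestPermutationThreshold:
    def _stat(self, seed=0):
        rng = np.random.default_rng(seed)
        table = rng.normal(size=(200, 45))

        def max_stat(perm):
            return float(np.max(table[:, perm[0]]))

        return max_stat

    def test_alpha_one_gives_minimum(self):
        thr, null = dm.permutation_threshold(self._stat(), n=45, n_perm=20,
                                             alpha=1.0, seed=3, return_null=True)
        assert thr == null.min()

    def test_monotone_non_increasing_in_alpha(self):
        thrs = [dm.permutation_threshold(self._stat(), n=45, n_perm=40,
                                         alpha=a, seed=3)
                for a in (0.05, 0.1, 0.25, 0.5, 1.0)]
        assert all(a >= b for a, b in zip(thrs, thrs[1:]))

    def test_alpha_below_resolution_rejected(self):
        with pytest.raises(ValueError):
            dm.permutation_threshold(self._stat(), n=45, n_perm=20, alpha=0.01)
        with pytest.raises(ValueError):
            dm.permutation_threshold(self._stat(), n=45, n_perm=10, alpha=0.5)

    def test_seeded_threshold_bit_reproducible(self, null_co_dataset):
        sc, ds = null_co_dataset
        pa, pb = pair_panels(ds)
        res = dm.cocom_scan(pa, pb, ds.abundance_matrix("a", "co"),
                            ds.abundance_matrix("b", "co"), ds.times)
        t1, n1 = dm.permutation_threshold(res.max_stat_fn, ds.n_pairs, n_perm=20,
                                          alpha=0.05, seed=9, return_null=True)
        t2, n2 = dm.permutation_threshold(res.max_stat_fn, ds.n_pairs, n_perm=20,
                                          alpha=0.05, seed=9, return_null=True)
        assert t1 == t2
        assert np.array_equal(n1, n2)

    def test_genome_wide_threshold_exceeds_single_test_quantile(self, null_mono_scan=None):
        sc = SimScenario(treatment="mono", h2=0.0, n_markers_a=50, n_markers_b=4,
                         seed=31)
        ds = simulate_dataset(sc)
        pa, _ = pair_panels(ds)
        res = dm.functional_mapping_scan(pa, ds.abundance_matrix("a", "mono"),
                                         ds.times)
        thr = dm.permutation_threshold(res.max_stat_fn, ds.n_pairs, n_perm=30,
                                       alpha=0.05, seed=4)
        assert thr >= stats.chi2.ppf(0.95, df=4)


class TestEffectTests:
    def _flat_fit(self, times):
        T = len(times)
        z = np.zeros(T)
        eff = GeneticEffects(mu_a=z, mu_b=z, direct_a=z, direct_b=z,
                             indirect_a_on_b=z, indirect_b_on_a=z,
                             epi_a=z, epi_b=z)
        return dm.DynamicFit(combo_params=None, cov=None, loglik=0.0,
                             loglik_null=0.0, lrt=0.0, converged=True, n_iter=1,
                             times=times, effects=eff)

    def test_zero_effect_curves_give_p_one(self, times):
        fit = self._flat_fit(times)
        null = [dm.effect_statistics(fit.effects, times) for _ in range(5)]
        table = dm.test_effects(fit, null)
        assert (table["statistic"] == 0.0).all()
        assert (table["p_value"] == 1.0).all()

    def test_missing_null_ensemble_rejected(self, times):
        with pytest.raises(ValueError):
            dm.test_effects(self._flat_fit(times), [])

    def test_statistics_stable_under_grid_refinement(self):
        t1 = np.linspace(0.0, 36.0, 19)
        t2 = np.linspace(0.0, 36.0, 181)

        def eff_on(t):
            z = np.zeros(len(t))
            c = np.sin(t / 6.0)
            return GeneticEffects(mu_a=z, mu_b=z, direct_a=c, direct_b=z,
                                  indirect_a_on_b=z, indirect_b_on_a=z,
                                  epi_a=0.5 * c, epi_b=z)

        s1 = dm.effect_statistics(eff_on(t1), t1)
        s2 = dm.effect_statistics(eff_on(t2), t2)
        assert s1["direct_a"] == pytest.approx(s2["direct_a"], rel=0.01)
        assert s1["epistasis_a"] == pytest.approx(s2["epistasis_a"], rel=0.01)

    def test_selective_power_for_pure_direct_architecture(self, times):
        # direct-only effect curves against a permutation-like null ensemble
        rng = np.random.default_rng(12)
        T = len(times)
        z = np.zeros(T)
        sig = 0.4 * np.sin(times / 10.0)
        eff = GeneticEffects(mu_a=z, mu_b=z, direct_a=sig, direct_b=sig,
                             indirect_a_on_b=z, indirect_b_on_a=z, epi_a=z, epi_b=z)
        fit = self._flat_fit(times)
        fit.effects = eff
        null = []
        for _ in range(99):
            c = rng.normal(0, 0.05, T)
            null.append(dm.effect_statistics(
                GeneticEffects(mu_a=z, mu_b=z, direct_a=c, direct_b=rng.normal(0, 0.05, T),
                               indirect_a_on_b=rng.normal(0, 0.05, T),
                               indirect_b_on_a=rng.normal(0, 0.05, T),
                               epi_a=rng.normal(0, 0.05, T), epi_b=rng.normal(0, 0.05, T)),
                times))
        table = dm.test_effects(fit, null).set_index("effect")
        assert table.loc["direct", "p_value"] <= 0.01
        assert table.loc["epistasis", "p_value"] > 0.05


class TestGenotypeCurveContrasts:
    def test_identical_treatments_zero_sensitivity(self, times):
        c = {0: np.sin(times), 1: np.cos(times)}
        out = dm.genotype_curve_contrasts(c, dict(c))
        assert np.allclose(out["sensitivity"][0], 0.0)
        assert np.allclose(out["sensitivity"][1], 0.0)

    def test_effect_curves_antisymmetric_under_allele_swap(self, times):
        mono = {0: np.sin(times), 1: np.cos(times)}
        co = {0: 2 * np.sin(times), 1: 2 * np.cos(times)}
        out = dm.genotype_curve_contrasts(mono, co)
        swapped = dm.genotype_curve_contrasts({0: mono[1], 1: mono[0]},
                                              {0: co[1], 1: co[0]})
        np.testing.assert_allclose(out["effect_mono"], -swapped["effect_mono"])
        np.testing.assert_allclose(out["effect_co"], -swapped["effect_co"])

    def test_effect_difference_equals_half_sensitivity_difference(self, times):
        rng = np.random.default_rng(2)
        mono = {0: rng.normal(size=len(times)), 1: rng.normal(size=len(times))}
        co = {0: rng.normal(size=len(times)), 1: rng.normal(size=len(times))}
        out = dm.genotype_curve_contrasts(mono, co)
        lhs = out["effect_co"] - out["effect_mono"]
        rhs = 0.5 * (out["sensitivity"][1] - out["sensitivity"][0])
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_missing_genotype_rejected(self, times):
        with pytest.raises(ValueError):
            dm.genotype_curve_contrasts({0: times}, {0: times, 1: times})
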