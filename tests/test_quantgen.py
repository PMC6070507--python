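"""Quarter-contrast effect decomposition and variance components.

The brute-force oracle solves the 4x4 linear system of the combo-value
table directly and is kept independent of the implementation under test.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cocom.quantgen import (
    COMBO_ORDER,
    ComboValues,
    GeneticEffects,
    compose_effects,
    decompose_effects,
    multi_locus_heritability,
    variance_components,
)

# design matrix of the combo-value table: columns (mean, own, partner, epi),
# rows in COMBO_ORDER; +/-1 contrast codes with uppercase allele = +1
_DESIGN = np.array([
    [1, 1, 1, 1],     # AB
    [1, 1, -1, -1],   # Ab
    [1, -1, 1, -1],   # aB
    [1, -1, -1, 1],   # ab
], dtype=float)


def oracle_solve(values4):
    """Brute-force inversion of the 4x4 combo-value system."""
    return np.linalg.solve(_DESIGN, np.asarray(values4, dtype=float))


class TestDecompose:
    def test_constant_combos_only_mean(self):
        c = ComboValues(species_a=np.full((4, 3), 2.5), species_b=np.full((4, 3), -1.0))
        eff = decompose_effects(c)
        np.testing.assert_array_equal(eff.mu_a, 2.5)
        np.testing.assert_array_equal(eff.mu_b, -1.0)
        for curve in (eff.direct_a, eff.direct_b, eff.indirect_a_on_b,
                      eff.indirect_b_on_a, eff.epi_a, eff.epi_b):
            np.testing.assert_array_equal(curve, 0.0)

    def test_worked_example_matches_linear_oracle(self):
        vals = [4.0, 2.0, 2.0, 0.0]
        mean, own, partner, epi = oracle_solve(vals)
        assert (mean, own, partner, epi) == (2.0, 1.0, 1.0, 0.0)
        c = ComboValues(species_a=np.array(vals)[:, None],
                        species_b=np.zeros((4, 1)))
        eff = decompose_effects(c)
        assert eff.mu_a[0] == mean
        assert eff.direct_a[0] == own
        assert eff.indirect_b_on_a[0] == partner
        assert eff.epi_a[0] == epi

    def test_pure_epistasis_contrast(self):
        vals = [1.0, -1.0, -1.0, 1.0]
        mean, own, partner, epi = oracle_solve(vals)
        assert (mean, own, partner, epi) == (0.0, 0.0, 0.0, 1.0)
        c = ComboValues(species_a=np.array(vals)[:, None], species_b=np.zeros((4, 1)))
        eff = decompose_effects(c)
        assert eff.direct_a[0] == 0.0
        assert eff.indirect_b_on_a[0] == 0.0
        assert eff.epi_a[0] == 1.0
        assert eff.mu_a[0] == 0.0

    @given(st.lists(st.floats(-1e6, 1e6), min_size=8, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle_for_random_values(self, vals):
        va, vb = np.array(vals[:4]), np.array(vals[4:])
        eff = decompose_effects(ComboValues(species_a=va[:, None], species_b=vb[:, None]))
        mean_a, own_a, partner_a, epi_a = oracle_solve(va)
        mean_b, own_b, partner_b, epi_b = oracle_solve(vb)
        assert eff.mu_a[0] == pytest.approx(mean_a, rel=1e-12, abs=1e-9)
        assert eff.direct_a[0] == pytest.approx(own_a, rel=1e-12, abs=1e-9)
        assert eff.indirect_b_on_a[0] == pytest.approx(partner_a, rel=1e-12, abs=1e-9)
        assert eff.epi_a[0] == pytest.approx(epi_a, rel=1e-12, abs=1e-9)
        # species B: own-locus contrast is the B locus
        assert eff.direct_b[0] == pytest.approx(partner_b, rel=1e-12, abs=1e-9)
        assert eff.indirect_a_on_b[0] == pytest.approx(own_b, rel=1e-12, abs=1e-9)


class TestComposeRoundTrip:
    @given(st.lists(st.floats(-1e8, 1e8), min_size=8, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_exact(self, vals):
        va, vb = np.array(vals[:4]), np.array(vals[4:])
        c = ComboValues(species_a=va[:, None], species_b=vb[:, None])
        back = compose_effects(decompose_effects(c))
        # exact up to rounding at the scale of the inputs (the contrasts sum
        # and re-difference the four values)
        scale_a = max(np.max(np.abs(va)), 1e-300)
        scale_b = max(np.max(np.abs(vb)), 1e-300)
        np.testing.assert_allclose(back.species_a, c.species_a, atol=4e-16 * scale_a)
        np.testing.assert_allclose(back.species_b, c.species_b, atol=4e-16 * scale_b)

    def test_zero_effects_compose_to_mean(self):
        z = np.zeros(5)
        eff = GeneticEffects(mu_a=np.full(5, 3.0), mu_b=np.full(5, 1.0),
                             direct_a=z, direct_b=z, indirect_a_on_b=z,
                             indirect_b_on_a=z, epi_a=z, epi_b=z)
        c = compose_effects(eff)
        np.testing.assert_array_equal(c.species_a, 3.0)
        np.testing.assert_array_equal(c.species_b, 1.0)

    def test_compose_of_worked_example(self):
        z = np.zeros(1)
        eff = GeneticEffects(mu_a=np.array([2.0]), mu_b=z, direct_a=np.array([1.0]),
                             direct_b=z, indirect_a_on_b=z,
                             indirect_b_on_a=np.array([1.0]), epi_a=z, epi_b=z)
        np.testing.assert_array_equal(compose_effects(eff).species_a.ravel(),
                                      [4.0, 2.0, 2.0, 0.0])

    def test_constant_shift_moves_only_mean(self):
        rng = np.random.default_rng(0)
        va = rng.normal(size=(4, 6))
        c0 = ComboValues(species_a=va, species_b=va * 0)
        c1 = ComboValues(species_a=va + 17.0, species_b=va * 0)
        e0, e1 = decompose_effects(c0), decompose_effects(c1)
        np.testing.assert_allclose(e1.mu_a, e0.mu_a + 17.0)
        np.testing.assert_allclose(e1.direct_a, e0.direct_a)
        np.testing.assert_allclose(e1.epi_a, e0.epi_a)


def _effects_a(direct, indirect, epi, mean=0.0, T=1):
    z = np.zeros(T)
    return GeneticEffects(mu_a=np.full(T, mean), mu_b=z,
                          direct_a=np.full(T, direct), direct_b=z,
                          indirect_a_on_b=z, indirect_b_on_a=np.full(T, indirect),
                          epi_a=np.full(T, epi), epi_b=z)


class TestVarianceComponents:
    def test_equal_freq_unit_effects_split_half_half(self):
        vc = variance_components(_effects_a(1.0, 1.0, 0.0), "a", pheno_var=10.0)
        assert vc.prop_direct[0] == pytest.approx(0.5)
        assert vc.prop_indirect[0] == pytest.approx(0.5)
        assert vc.prop_epistatic[0] == pytest.approx(0.0)

    def test_zero_effects_zero_heritability(self):
        vc = variance_components(_effects_a(0.0, 0.0, 0.0, mean=5.0), "a", pheno_var=2.0)
        assert vc.h2[0] == 0.0
        assert vc.total_genetic[0] == 0.0

    @given(st.floats(-3, 3), st.floats(-3, 3), st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_equal_freq_components_sum_to_between_combo_variance(self, d, i, e):
        eff = _effects_a(d, i, e)
        vc = variance_components(eff, "a", pheno_var=1e6)
        combos = compose_effects(eff).species_a[:, 0]
        brute = np.mean((combos - combos.mean()) ** 2)
        assert vc.direct[0] + vc.indirect[0] + vc.epistatic[0] == pytest.approx(
            brute, rel=1e-9, abs=1e-12)
        assert vc.total_genetic[0] == pytest.approx(brute, rel=1e-9, abs=1e-12)

    def test_observed_freq_total_is_weighted_combo_variance(self):
        eff = _effects_a(1.0, 0.5, -0.3, mean=2.0)
        freqs = np.array([0.4, 0.3, 0.2, 0.1])
        vc = variance_components(eff, "a", pheno_var=100.0, combo_freqs=freqs)
        combos = compose_effects(eff).species_a[:, 0]
        mbar = freqs @ combos
        brute = freqs @ (combos - mbar) ** 2
        assert vc.total_genetic[0] == pytest.approx(brute, rel=1e-9)
        assert vc.prop_direct[0] + vc.prop_indirect[0] + vc.prop_epistatic[0] \
            == pytest.approx(1.0)

    def test_h2_between_zero_and_one(self):
        vc = variance_components(_effects_a(1.0, 1.0, 1.0), "a", pheno_var=0.5)
        assert 0.0 <= vc.h2[0] <= 1.0


class TestMultiLocus:
    def test_single_pair_is_its_h2(self):
        vc = variance_components(_effects_a(1.0, 0.0, 0.0), "a", pheno_var=10.0)
        h2, share = multi_locus_heritability([vc])
        assert h2[0] == pytest.approx(vc.h2[0])

    def test_two_identical_pairs_double(self):
        vc = variance_components(_effects_a(1.0, 0.0, 0.0), "a", pheno_var=10.0)
        h2, _ = multi_locus_heritability([vc, vc])
        assert h2[0] == pytest.approx(2.0 * vc.h2[0])

    def test_aggregate_share_is_variance_weighted_mean(self):
        v1 = variance_components(_effects_a(1.0, 1.0, 0.0), "a", pheno_var=10.0)
        v2 = variance_components(_effects_a(2.0, 0.0, 0.0), "a", pheno_var=10.0)
        _, share = multi_locus_heritability([v1, v2])
        tot1 = v1.total_genetic[0]
        tot2 = v2.total_genetic[0]
        expect = (v1.indirect[0] + v1.epistatic[0]) / (tot1 + tot2)
        assert share[0] == pytest.approx(expect)

    def test_inconsistent_pheno_var_rejected(self):
        v1 = variance_components(_effects_a(1.0, 0.0, 0.0), "a", pheno_var=10.0)
        v2 = variance_components(_effects_a(1.0, 0.0, 0.0), "a", pheno_var=20.0)
        with pytest.raises(ValueError):
            multi_locus_heritability([v1, v2])
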